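#!/usr/bin/env python
"""Censored-regression medication adjustment and covariate
residualization (writes results/run/residuals.csv)."""

import importlib

common = importlib.import_module("00_common")

if __name__ == "__main__":
    manifest = common.run_stages("adjust")
    s = manifest["stages"]["adjust"]
    print(f"adjusted {s['n_rows_in']} visit rows -> "
          f"{s['n_individuals_out']} individuals x {s['n_visits']} visits")
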