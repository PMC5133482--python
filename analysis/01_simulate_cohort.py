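#!/usr/bin/env python
"""Simulate the full-scale synthetic cohort (writes results/run/data/)."""

import importlib

common = importlib.import_module("00_common")

if __name__ == "__main__":
    manifest = common.run_stages("simulate")
    s = manifest["stages"]["simulate"]
    print(f"simulated {s['n_families']} families, "
          f"{s['n_individuals']} individuals, {s['n_snps']} SNPs")
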