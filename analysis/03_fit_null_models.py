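#!/usr/bin/env python
"""Fit the null AR and LG SEMs (writes results/run/fit_null_{ar,lg}.json)."""

import importlib

common = importlib.import_module("00_common")

if __name__ == "__main__":
    manifest = common.run_stages("adjust", "fit-null")
    for kind, s in manifest["stages"]["fit-null"].items():
        print(f"{kind}: loglik={s['loglik']:.2f} converged={s['converged']}")
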