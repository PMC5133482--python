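#!/usr/bin/env python
"""Cross-model concordance of the AR and LG scans
(writes results/run/compare.tsv)."""

import importlib

common = importlib.import_module("00_common")

if __name__ == "__main__":
    manifest = common.run_stages("adjust", "fit-null", "scan", "compare")
    s = manifest["stages"]["compare"]
    print(f"rank correlation={s['rank_correlation']:.3f} "
          f"shared suggestive hits={s['shared_hit_ids']}")
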