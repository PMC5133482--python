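"""Shared plumbing for the numbered analysis scripts."""

import logging
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from pedsem.pipeline import RunConfig, run_pipeline  # noqa: E402


def run_stages(*stages):
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    cfg = RunConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    cfg.outdir = str(ROOT / cfg.outdir)
    for attr in ("ped_file", "pheno_file", "geno_file"):
        val = getattr(cfg, attr)
        if val is not None:
            setattr(cfg, attr, str(ROOT / val))
    cfg.stages = stages
    return run_pipeline(cfg)
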