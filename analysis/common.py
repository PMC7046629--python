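"""Shared setup for the numbered analysis drivers.

Every driver works out of one run directory (default ``results/analysis``)
so they can be executed in order:

    python analysis/01_simulate.py
    python analysis/02_differential_expression.py
    python analysis/03_motif_enrichment.py
    python analysis/04_tf_classification.py
    python analysis/05_target_prediction.py
    python analysis/06_ground_truth_evaluation.py
"""

import argparse
import logging
import sys

from astrotf.cli import _resolve_sim_inputs
from astrotf.pipeline import PipelineConfig

DEFAULT_OUTDIR = "results/analysis"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=42, help="master random seed")
    ap.add_argument("--outdir", default=DEFAULT_OUTDIR, help="run directory")
    return ap.parse_args()


def build_config(args: argparse.Namespace) -> PipelineConfig:
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(message)s")
    cfg = PipelineConfig(outdir=args.outdir, seed=args.seed)
    return _resolve_sim_inputs(cfg)
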