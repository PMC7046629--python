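"""Step 6 — score every call against the planted ground-truth manifest.

Recomputes the full in-memory analysis and writes evaluation.json with DEG
Jaccard per region, universal/region TF recovery and target precision/recall.
"""

import json

from astrotf.pipeline import _load_inputs, analyze
from common import build_config, parse_args


def main():
    args = parse_args(__doc__)
    cfg = build_config(args)
    cm, contigs, bed, motifs, truth = _load_inputs(cfg)
    if truth is None:
        raise SystemExit("no ground_truth.json found; run 01_simulate.py first")
    result = analyze(cm, contigs, bed, motifs, cfg, truth=truth)
    comparison = result.report.ground_truth_comparison
    with open(f"{cfg.outdir}/evaluation.json", "w") as fh:
        json.dump(comparison, fh, indent=1, default=str)
    print(f"DEG Jaccard per region: "
          f"{ {r: round(j, 3) for r, j in comparison['deg_jaccard'].items()} }")
    print(f"universal TF recall: {comparison['universal']['recall']} "
          f"(min region frequency "
          f"{comparison['universal']['min_region_frequency']:.3f})")
    print(f"region top-TF match rate: {comparison['region_tfs']['top_match_rate']}")
    print(f"target precision {comparison['targets']['precision']:.3f}, "
          f"recall {comparison['targets']['recall']:.3f}")
    print(f"written to {cfg.outdir}/evaluation.json")


if __name__ == "__main__":
    main()
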