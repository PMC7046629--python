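"""Step 2 — RPM normalization, PCA QC and one-vs-rest DEG calling.

Writes deg_table.tsv, pca.tsv and deg_summary.json into the run directory.
"""

import json

from astrotf.pipeline import stage_degs
from common import build_config, parse_args


def main():
    args = parse_args(__doc__)
    cfg = build_config(args)
    table = stage_degs(cfg)
    with open(f"{cfg.outdir}/deg_summary.json") as fh:
        summary = json.load(fh)
    print(f"DEG counts per region: {summary['deg_counts']}")
    print(f"pooled list: {summary['pooled_dedup']} genes "
          f"({summary['pooled_raw']} before dedup)")
    print(f"PC1/PC2 variance fractions: "
          f"{[round(f, 3) for f in summary['pca_variance_fractions'][:2]]}")
    print(f"DEG table ({int(table['is_deg'].sum())} DEG rows) at "
          f"{cfg.outdir}/deg_table.tsv")


if __name__ == "__main__":
    main()
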