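"""Step 5 — predict direct targets of each region's top TF.

A region DEG is a target when it is >2.5-fold up at p < 0.01 and carries a
zero-mismatch consensus hit within 2 kb of its TSS.  Writes targets.tsv plus
ChIP-qPCR candidate windows (primer_windows.bed / .fa).
"""

from astrotf.pipeline import stage_targets
from common import build_config, parse_args


def main():
    args = parse_args(__doc__)
    cfg = build_config(args)
    frame = stage_targets(cfg)
    if len(frame):
        per_region = frame.groupby("region").size().to_dict()
        print(f"predicted targets per region: {per_region}")
        top3 = frame.groupby("region").head(3)
        print("top 3 per region (by fold change):")
        for row in top3.itertuples(index=False):
            print(f"  {row.region}: {row.target_gene} "
                  f"(log2FC {row.log2fc:.2f}, offset {row.offset:+d})")
    else:
        print("no targets predicted")
    print(f"tables at {cfg.outdir}/targets.tsv and {cfg.outdir}/primer_windows.bed")


if __name__ == "__main__":
    main()
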