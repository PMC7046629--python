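"""Step 3 — hypergeometric motif enrichment in region and pooled DEG sets.

Writes enrichment.tsv (one row per motif per gene set, raw and BH-adjusted
p-values, ZOOPS counts and fold enrichment).
"""

from astrotf.pipeline import stage_enrich
from common import build_config, parse_args


def main():
    args = parse_args(__doc__)
    cfg = build_config(args)
    table = stage_enrich(cfg)
    hits = table[table["padj"] < cfg.enrich_p]
    print(f"{len(table)} motif x gene-set tests; "
          f"{len(hits)} significant at BH-adjusted p < {cfg.enrich_p}")
    pooled = hits[hits["gene_set"] == "pooled"]
    if len(pooled):
        print("enriched in the pooled DEG list:",
              ", ".join(sorted(pooled["motif"])))
    print(f"table at {cfg.outdir}/enrichment.tsv")


if __name__ == "__main__":
    main()
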