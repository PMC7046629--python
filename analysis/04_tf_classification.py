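"""Step 4 — classify TFs as universal or region-specific.

Universal: motif enriched in the pooled DEG list, present in >= 50% of every
region's DEGs, TF gene past the RPM gate everywhere.  Region-specific: motif
enriched in one region's DEGs with the TF itself >2-fold up (p < 0.01) there.
Writes universal_tfs.tsv and region_tfs.tsv.
"""

from astrotf.discovery import select_top_tf
from astrotf.pipeline import stage_discover
from common import build_config, parse_args


def main():
    args = parse_args(__doc__)
    cfg = build_config(args)
    universal, region_calls = stage_discover(cfg)
    for c in universal:
        print(f"universal TF {c.tf_gene} (motif {c.motif}): pooled p={c.pvalue:.3g}, "
              f"min region frequency {min(c.region_frequency.values()):.3f}")
    for region, calls in region_calls.items():
        top = select_top_tf(calls)
        label = (f"{top.tf_gene} (log2FC {top.tf_log2fc:.2f})" if top
                 else "none (no qualifying TF)")
        print(f"{region}: {len(calls)} candidate(s); top TF: {label}")
    print(f"tables at {cfg.outdir}/universal_tfs.tsv and {cfg.outdir}/region_tfs.tsv")


if __name__ == "__main__":
    main()
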