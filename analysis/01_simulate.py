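"""Step 1 — generate the synthetic regional astrocyte RNA-seq study.

Writes genome.fa, tss.bed, counts.tsv, samples.tsv, motifs.txt,
motif_tf_map.tsv and ground_truth.json under <outdir>/sim.
"""

from astrotf.pipeline import stage_simulate
from common import build_config, parse_args


def main():
    args = parse_args(__doc__)
    cfg = build_config(args)
    cfg = stage_simulate(cfg)
    print(f"synthetic study written under {cfg.outdir}/sim (seed {cfg.seed})")


if __name__ == "__main__":
    main()
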