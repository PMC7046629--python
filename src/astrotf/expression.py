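"""Count normalization, expression gating, one-vs-rest differential
expression, DEG calling and sample-level PCA.

The differential test is a self-contained negative-binomial Wald test with
median-of-ratios size factors: for each gene a method-of-moments dispersion
is estimated from within-group residuals (floored at 1e-8), the fold change
is the ratio of group means of normalized counts (pseudo-mean 0.5 added
before the ratio), and the two-sided p-value comes from the standard normal
tail of the Wald statistic on the log ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
PSEUDO_MEAN = 0.5


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample sheet."""

    counts: pd.DataFrame                      # genes x samples
    sample_region: dict[str, str]             # sample -> region label
    sample_replicate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_region)
        if missing:
            raise ValueError(f"samples without region labels: {sorted(missing)[:5]}")
        for region in self.regions:
            if len(self.samples_in(region)) < 2:
                raise ValueError(f"region {region} has fewer than 2 samples")
        if not self.sample_replicate:
            seen: dict[str, int] = {}
            for s in self.counts.columns:
                r = self.sample_region[s]
                seen[r] = seen.get(r, 0) + 1
                self.sample_replicate[s] = seen[r]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def regions(self) -> list[str]:
        seen = []
        for s in self.counts.columns:
            r = self.sample_region[s]
            if r not in seen:
                seen.append(r)
        return seen

    def samples_in(self, region: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_region[s] == region]

    # --- TSV round trips -------------------------------------------------
    def to_tsv(self, counts_path: str, sheet_path: str) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        sheet = pd.DataFrame({
            "sample": self.samples,
            "region": [self.sample_region[s] for s in self.samples],
            "replicate": [self.sample_replicate[s] for s in self.samples],
        })
        sheet.to_csv(sheet_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str, sheet_path: str) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path, sep="\t")
        extra = set(counts.columns) ^ set(sheet["sample"])
        if extra:
            raise ValueError(f"sample sheet does not match count columns: {sorted(extra)[:5]}")
        return cls(
            counts=counts,
            sample_region=dict(zip(sheet["sample"], sheet["region"])),
            sample_replicate=dict(zip(sheet["sample"], sheet["replicate"])),
        )


# ---------------------------------------------------------------------------
# Normalization and gating


def normalize_rpm(cm: CountMatrix) -> pd.DataFrame:
    """Reads-per-million: each sample column rescaled to sum to 1e6."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    return cm.counts * 1e6 / totals


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference over genes
    with all-positive counts)."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has all-positive counts; cannot compute size factors")
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def expression_gate(rpm: pd.DataFrame, cm: CountMatrix, region: str,
                    threshold: float = 5.0, min_reps: int = 2) -> pd.Series:
    """True iff >= min_reps replicates of the region have RPM strictly > threshold."""
    samples = cm.samples_in(region)
    if len(samples) < min_reps:
        raise ValueError(f"region {region} has fewer than {min_reps} samples")
    return (rpm[samples] > threshold).sum(axis=1) >= min_reps


# ---------------------------------------------------------------------------
# One-vs-rest differential expression


def _dispersion_trend(mean: np.ndarray, alpha: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Median dispersion as a function of mean expression.

    Genes are binned by log mean; the per-bin median of gene-wise estimates
    is interpolated back to every gene.  Serves as a lower envelope for the
    noisy per-gene moment estimates.
    """
    ok = (mean > 0) & np.isfinite(alpha)
    if ok.sum() < 10:
        med = float(np.median(alpha[ok])) if ok.any() else DISPERSION_FLOOR
        return np.full_like(alpha, max(med, DISPERSION_FLOOR))
    logm = np.log(mean[ok])
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, len(edges) - 2)
    centers, medians = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() >= 3:
            centers.append(float(logm[sel].mean()))
            medians.append(float(np.median(alpha[ok][sel])))
    if not centers:
        med = float(np.median(alpha[ok]))
        return np.full_like(alpha, max(med, DISPERSION_FLOOR))
    out = np.full_like(alpha, DISPERSION_FLOOR)
    with np.errstate(divide="ignore"):
        out[ok] = np.interp(logm, centers, medians)
    # genes with zero mean keep the floor
    return np.maximum(out, DISPERSION_FLOOR)


def one_vs_rest_de(cm: CountMatrix, region: str,
                   sf: pd.Series | None = None) -> pd.DataFrame:
    """NB Wald test of one region's samples against all other samples.

    Returns a DataFrame indexed by gene with columns log2fc, pvalue,
    dispersion and all_zero.  Genes with all-zero counts get log2fc 0,
    p-value 1 and the all_zero flag.
    """
    in_region = cm.samples_in(region)
    out_region = [s for s in cm.samples if s not in in_region]
    if len(in_region) < 2 or len(out_region) < 2:
        raise ValueError("need >= 2 samples in the region and >= 2 in the rest")
    if sf is None:
        sf = size_factors(cm.counts)
    q = cm.counts / sf

    qa = q[in_region].to_numpy()
    qb = q[out_region].to_numpy()
    na, nb = qa.shape[1], qb.shape[1]
    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    # mean inverse size factor per group: Var(count/s) = mu/s + alpha*mu^2
    ca = float(np.mean(1.0 / sf[in_region].to_numpy()))
    cb = float(np.mean(1.0 / sf[out_region].to_numpy()))

    # method-of-moments dispersion pooled over within-REGION residuals:
    # the rest group mixes regions with different means, so its pooled
    # variance would confound real cross-region structure with dispersion
    num = np.zeros(len(q))
    den = np.zeros(len(q))
    for other in cm.regions:
        cols = cm.samples_in(other)
        if len(cols) < 2:
            continue
        qr = q[cols].to_numpy()
        mu_r = qr.mean(axis=1)
        var_r = qr.var(axis=1, ddof=1)
        c_r = float(np.mean(1.0 / sf[cols].to_numpy()))
        num += (len(cols) - 1) * (var_r - mu_r * c_r)
        den += (len(cols) - 1) * mu_r ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    # moderate the noisy gene-wise estimate against a mean-dispersion trend
    # (max of gene-wise and trend, as DE tools do): with a handful of
    # replicates the raw moment estimator's downward fluctuations would
    # otherwise inflate the Wald statistic well past its nominal level
    alpha = np.maximum(alpha, _dispersion_trend(mu_a * na / (na + nb)
                                                + mu_b * nb / (na + nb), alpha))

    log2fc = np.log2((mu_a + PSEUDO_MEAN) / (mu_b + PSEUDO_MEAN))
    var_log_a = (mu_a * ca / na + alpha * mu_a ** 2 / na) / (mu_a + PSEUDO_MEAN) ** 2
    var_log_b = (mu_b * cb / nb + alpha * mu_b ** 2 / nb) / (mu_b + PSEUDO_MEAN) ** 2
    se = np.sqrt(var_log_a + var_log_b)
    lnfc = np.log((mu_a + PSEUDO_MEAN) / (mu_b + PSEUDO_MEAN))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lnfc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.minimum(pvalue, 1.0)

    all_zero = (cm.counts.to_numpy().sum(axis=1) == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalue = np.where(all_zero, 1.0, pvalue)

    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "dispersion": alpha, "all_zero": all_zero},
        index=cm.counts.index,
    )


# ---------------------------------------------------------------------------
# DEG calling


def call_degs(cm: CountMatrix, fc_threshold: float = 1.5, p_threshold: float = 0.01,
              rpm_threshold: float = 5.0, min_reps: int = 2) -> pd.DataFrame:
    """Per-region one-vs-rest DEG table.

    A gene is a DEG in a region iff it passes the RPM expression gate there,
    |fold change| > fc_threshold and p < p_threshold.  Long-format columns:
    gene, region, log2fc, pvalue, rpm_pass, is_deg, direction.
    """
    rpm = normalize_rpm(cm)
    sf = size_factors(cm.counts)
    lfc_cut = np.log2(fc_threshold)
    frames = []
    for region in cm.regions:
        de = one_vs_rest_de(cm, region, sf=sf)
        gate = expression_gate(rpm, cm, region, threshold=rpm_threshold, min_reps=min_reps)
        is_deg = gate & (de["log2fc"].abs() > lfc_cut) & (de["pvalue"] < p_threshold)
        frames.append(pd.DataFrame({
            "gene": de.index,
            "region": region,
            "log2fc": de["log2fc"].to_numpy(),
            "pvalue": de["pvalue"].to_numpy(),
            "rpm_pass": gate.to_numpy(),
            "is_deg": is_deg.to_numpy(),
            "direction": np.where(de["log2fc"] >= 0, "up", "down"),
        }))
    return pd.concat(frames, ignore_index=True)


def deg_sets(deg_table: pd.DataFrame) -> dict[str, set[str]]:
    """region -> set of DEG gene ids."""
    return {
        region: set(sub.loc[sub["is_deg"], "gene"])
        for region, sub in deg_table.groupby("region", sort=False)
    }


def deg_direction_fractions(deg_table: pd.DataFrame) -> pd.DataFrame:
    """Per-region DEG counts and up/down fractions."""
    rows = []
    for region, sub in deg_table.groupby("region", sort=False):
        degs = sub[sub["is_deg"]]
        n = len(degs)
        up = int((degs["direction"] == "up").sum())
        rows.append({"region": region, "n_degs": n, "n_up": up, "n_down": n - up,
                     "frac_up": up / n if n else float("nan"),
                     "frac_down": (n - up) / n if n else float("nan")})
    return pd.DataFrame(rows)


def pool_degs(region_sets: dict[str, set[str]] | pd.DataFrame):
    """Pool per-region DEG sets into one deduplicated list.

    Accepts either a region->gene-set mapping or a DEG table.  Returns
    ``(pooled_list, raw_sum, dedup_size)`` where raw_sum is the sum of the
    per-region sizes before deduplication.
    """
    if isinstance(region_sets, pd.DataFrame):
        region_sets = deg_sets(region_sets)
    raw_sum = sum(len(s) for s in region_sets.values())
    pooled: list[str] = []
    seen: set[str] = set()
    for region in region_sets:
        for g in sorted(region_sets[region]):
            if g not in seen:
                seen.add(g)
                pooled.append(g)
    return pooled, raw_sum, len(pooled)


# ---------------------------------------------------------------------------
# PCA QC


def sample_pca(rpm: pd.DataFrame, min_expr: float = 1.0, n_components: int | None = None):
    """PCA of samples on log2(RPM+1) of genes with mean RPM > min_expr.

    Gene-centered; returns ``(coords, variance_fractions)`` where coords is
    a samples x PCs DataFrame and the fractions sum to 1.
    """
    if rpm.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA")
    kept = rpm[rpm.mean(axis=1) > min_expr]
    if kept.shape[0] < 2:
        raise ValueError("fewer than 2 genes retained after expression filter")
    x = np.log2(kept.to_numpy() + 1.0)
    x = x - x.mean(axis=1, keepdims=True)
    # SVD over samples: columns of v are sample-space directions
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    if total == 0:
        # identical profiles: all variance fractions on PC1 by convention
        frac = np.zeros(min(x.shape))
        frac[0] = 1.0
        coords = np.zeros((x.shape[1], len(frac)))
    else:
        frac = s ** 2 / total
        coords = (vt * s[:, None]).T
    k = n_components or coords.shape[1]
    coords = pd.DataFrame(coords[:, :k], index=rpm.columns,
                          columns=[f"PC{i+1}" for i in range(min(k, coords.shape[1]))])
    return coords, frac[:k]
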