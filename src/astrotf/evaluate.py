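"""Recovery metrics against a planted ground-truth manifest."""

from __future__ import annotations

import pandas as pd

from .simulate import GroundTruth


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _as_list(x):
    return x if isinstance(x, list) else [x]


def deg_recovery(truth: GroundTruth, called_sets: dict[str, set]) -> dict[str, float]:
    """Per-region Jaccard between called and true DEG sets."""
    return {
        region: jaccard(called_sets.get(region, set()), truth.region_deg_union(region))
        for region in truth.deg_sets
    }


def universal_recovery(truth: GroundTruth, universal_calls) -> dict:
    called = {c.tf_gene for c in universal_calls}
    planted = set(truth.universal_tfs)
    decoy_tfs = {tf for m, tf in truth.motif_tf.items() if m.startswith("M_DECOY")}
    return {
        "recall": len(called & planted) / len(planted) if planted else float("nan"),
        "n_called": len(called),
        "decoy_calls": sorted(called & decoy_tfs),
        "min_region_frequency": min(
            (min(c.region_frequency.values()) for c in universal_calls
             if c.tf_gene in planted), default=float("nan")),
    }


def region_tf_recovery(truth: GroundTruth, region_calls: dict) -> dict:
    """Per-region: is the planted TF the top call, and is any decoy a top call."""
    decoy_tfs = {tf for m, tf in truth.motif_tf.items() if m.startswith("M_DECOY")}
    per_region, matches, n_regions = {}, 0, 0
    decoy_top = []
    for region, planted in truth.region_tfs.items():
        planted = _as_list(planted)
        calls = region_calls.get(region, [])
        top = next((c for c in calls if c.is_top), None)
        match = top is not None and top.tf_gene in planted
        per_region[region] = {
            "planted": planted, "top": top.tf_gene if top else None, "match": match,
        }
        if top and top.tf_gene in decoy_tfs:
            decoy_top.append(top.tf_gene)
        matches += match
        n_regions += 1
    return {
        "per_region": per_region,
        "top_match_rate": matches / n_regions if n_regions else float("nan"),
        "decoy_top_calls": decoy_top,
    }


def target_recovery(truth: GroundTruth, targets_by_region: dict) -> dict:
    """Precision/recall of predicted targets per region and pooled."""
    per_region = {}
    tp = fp = fn = 0
    for region, planted_tf in truth.region_tfs.items():
        planted_tf = _as_list(planted_tf)[0]
        true_targets = set(truth.targets.get(planted_tf, []))
        predicted = {t.target_gene for t in targets_by_region.get(region, [])}
        tpr = len(predicted & true_targets)
        per_region[region] = {
            "precision": tpr / len(predicted) if predicted else float("nan"),
            "recall": tpr / len(true_targets) if true_targets else float("nan"),
            "n_predicted": len(predicted), "n_true": len(true_targets),
        }
        tp += tpr
        fp += len(predicted - true_targets)
        fn += len(true_targets - predicted)
    return {
        "per_region": per_region,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
    }
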