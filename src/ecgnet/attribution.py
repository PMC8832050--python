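"""Lead-level interpretability: SE attention weights and Grad-CAM.

Two complementary views of "which leads mattered":

* **SE gates** — the lead-stage squeeze-excitation emits one logistic gate
  per lead; each convolutional branch emits one gate per feature channel.
  Channel gates are not lead-indexed, so the per-scale lead weights reported
  here are the input-stage lead gates composed with an energy-weighted
  average of the branch's channel gates per lead (see ``extract_se_weights``).
  Output metadata labels this interpretation explicitly.

* **Grad-CAM** — for a chosen class, the gradient of the pre-softmax class
  score with respect to each branch's last convolutional feature map is
  averaged over time and leads to give one weight per channel; the rectified
  weighted channel sum is the branch relevance map.  Branch maps are
  interpolated along time to the input length (the lead axis is never
  interpolated) and fused across branches (mean by default, max optional).
  Per-lead scores are time-means of the fused map; ties in the ranking break
  by canonical lead order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architecture import EcgNetModel
from .io_formats import CANONICAL_LEADS

__all__ = ["LeadWeights", "AttributionMap", "extract_se_weights", "grad_cam",
           "lead_ranking_report", "save_lead_weights_csv"]

SE_STAGES = ("input", "scale3", "scale5", "scale7")


@dataclass
class LeadWeights:
    """Per-lead attention weights for one SE stage; values in (0, 1)."""

    stage: str
    weights: np.ndarray  # (12,) in canonical lead order
    beat_ref: str = ""
    class_ref: str = ""
    interpretation: str = "direct lead-stage gate"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(CANONICAL_LEADS),):
            raise ValueError("lead weights must have exactly 12 values")

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "weights": {l: float(w) for l, w in zip(CANONICAL_LEADS, self.weights)},
            "beat_ref": self.beat_ref,
            "class_ref": self.class_ref,
            "interpretation": self.interpretation,
        }


@dataclass
class AttributionMap:
    """Grad-CAM relevance over time x leads with per-lead aggregation."""

    relevance: np.ndarray   # (T, 12), non-negative
    lead_scores: np.ndarray  # (12,) time-means
    ranking: tuple          # lead names, descending score
    class_index: int = 0
    beat_ref: str = ""

    def __post_init__(self):
        self.relevance = np.asarray(self.relevance, dtype=np.float64)
        if np.any(self.relevance < 0):
            raise ValueError("relevance must be non-negative (post-rectification)")


def _rank_leads(scores: np.ndarray) -> tuple:
    # stable sort on negated scores: ties keep canonical lead order
    order = np.argsort(-scores, kind="stable")
    return tuple(CANONICAL_LEADS[i] for i in order)


def extract_se_weights(model: EcgNetModel, beat: np.ndarray,
                       class_ref: str = "", beat_ref: str = "") -> list[LeadWeights]:
    """Per-lead SE weights at the input stage and at each kernel scale.

    ``beat`` is one (651, 12) window.  The input stage reads the lead-axis
    gates directly.  For scale k the branch's channel gates ``g_c`` are
    projected to leads through the feature-map energy: the per-lead weight is
    ``g_input[l] * sum_c(g_c * e_cl) / sum_c(e_cl)`` where ``e_cl`` is the
    time-mean squared activation of channel c at lead l — a convex
    combination of logistic gates scaled by a logistic gate, hence in (0, 1).
    """
    beat = np.asarray(beat)
    if beat.ndim == 2:
        beat = beat[None, ..., None]
    elif beat.ndim == 3:
        beat = beat[None, ...]
    _, handles = model.forward(beat, train=False)
    lead_gates = handles["se_input"].data[0]  # (12,)
    out = [LeadWeights("input", lead_gates, beat_ref, class_ref)]
    for k in model.cfg.branch_kernels:
        chan_gates = handles[f"se_scale{k}"].data[0]          # (F,)
        feat = handles[f"lastconv_scale{k}"].data[0]          # (T, 12, F)
        energy = (feat**2).mean(axis=0)                       # (12, F)
        denom = energy.sum(axis=1)
        proj = np.where(denom > 0, (energy * chan_gates).sum(axis=1) /
                        np.maximum(denom, np.finfo(float).tiny), chan_gates.mean())
        out.append(LeadWeights(
            f"scale{k}", lead_gates * proj, beat_ref, class_ref,
            interpretation=("input-stage lead gates composed with "
                            "energy-weighted branch channel gates"),
        ))
    return out


def _interp_time(map2d: np.ndarray, target_len: int) -> np.ndarray:
    """Linear interpolation along time only; leads are preserved."""
    t = map2d.shape[0]
    if t == target_len:
        return map2d
    src = np.linspace(0.0, 1.0, t)
    dst = np.linspace(0.0, 1.0, target_len)
    return np.stack([np.interp(dst, src, map2d[:, j]) for j in range(map2d.shape[1])],
                    axis=1)


def grad_cam(model: EcgNetModel, beat: np.ndarray, class_index: int,
             fusion: str = "mean", beat_ref: str = "") -> AttributionMap:
    """Grad-CAM relevance of one beat for one class.

    The class score is the pre-softmax logit (softmax saturation flattens
    gradients).  Per branch: channel weights are the gradient averaged over
    time and leads; the map is the rectified weighted channel sum.  Branch
    maps are fused by ``fusion`` ('mean' or 'max').
    """
    if fusion not in ("mean", "max"):
        raise ValueError("fusion must be 'mean' or 'max'")
    beat = np.asarray(beat)
    if beat.ndim == 2:
        beat = beat[None, ..., None]
    elif beat.ndim == 3:
        beat = beat[None, ...]
    logits, handles = model.forward(beat, train=False)
    if not 0 <= class_index < model.cfg.n_classes:
        raise ValueError(f"class_index {class_index} out of range")
    seed = np.zeros_like(logits.data)
    seed[0, class_index] = 1.0
    logits.backward(seed)

    maps = []
    for k in model.cfg.branch_kernels:
        feat = handles[f"lastconv_scale{k}"]
        grad = feat.grad
        if grad is None or not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                f"non-finite or missing gradient on branch k={k} feature map"
            )
        weights = grad[0].mean(axis=(0, 1))             # gradient average -> (F,)
        cam = np.einsum("tlf,f->tl", feat.data[0].astype(np.float64), weights)
        cam = np.maximum(cam, 0.0)                      # rectify
        maps.append(_interp_time(cam, model.cfg.input_length))
    fused = np.mean(maps, axis=0) if fusion == "mean" else np.max(maps, axis=0)
    lead_scores = fused.mean(axis=0)
    return AttributionMap(fused, lead_scores, _rank_leads(lead_scores),
                          class_index, beat_ref)


def lead_ranking_report(maps_by_class: dict, taxonomy=None) -> dict:
    """Per-class lead ranking from mean lead scores across supplied maps.

    ``maps_by_class`` maps a class name to a list of AttributionMap.  Returns
    a JSON-ready dict: per class, the mean score per lead and the descending
    ranking (ties broken by canonical lead order).
    """
    report = {}
    for cls, maps in maps_by_class.items():
        if not maps:
            raise ValueError(f"no attribution maps supplied for class {cls!r}")
        scores = np.mean([m.lead_scores for m in maps], axis=0)
        report[cls] = {
            "mean_lead_scores": {l: float(s) for l, s in zip(CANONICAL_LEADS, scores)},
            "ranking": list(_rank_leads(scores)),
            "n_beats": len(maps),
        }
    return report


def save_lead_weights_csv(weights: list[LeadWeights], path) -> Path:
    """Polar-plot-ready CSV: one row per (stage, lead, weight)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stage", "lead", "weight", "interpretation"])
        for lw in weights:
            for lead, w in zip(CANONICAL_LEADS, lw.weights):
                writer.writerow([lw.stage, lead, f"{w:.6f}", lw.interpretation])
    return path
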