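"""Ground-truth validation helpers for phantom runs.

Used to score a segmentation against a phantom's truth label image: nuclei
are matched one-to-one greedily by descending intersection-over-union.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse


def match_nuclei(
    truth_labels: np.ndarray, pred_labels: np.ndarray
) -> dict[int, tuple[int, float]]:
    """Greedy one-to-one matching of truth to predicted nuclei by IoU.

    Returns a mapping truth_id -> (pred_id, iou); unmatched truth ids are
    absent.  Greedy on descending IoU with deterministic tie-breaking.
    """
    sel = (truth_labels > 0) | (pred_labels > 0)
    t = truth_labels[sel].astype(np.int64)
    p = pred_labels[sel].astype(np.int64)
    overlap = sparse.coo_matrix((np.ones(t.size, dtype=np.int64), (t, p)))
    overlap.sum_duplicates()
    t_areas = np.bincount(truth_labels.ravel())
    p_areas = np.bincount(pred_labels.ravel())
    pairs = []
    for ti, pi, inter in zip(overlap.row, overlap.col, overlap.data):
        if ti == 0 or pi == 0:
            continue
        union = t_areas[ti] + p_areas[pi] - inter
        pairs.append((inter / union, int(ti), int(pi)))
    pairs.sort(reverse=True)
    matched: dict[int, tuple[int, float]] = {}
    used_p: set[int] = set()
    for iou, ti, pi in pairs:
        if ti in matched or pi in used_p:
            continue
        matched[ti] = (pi, float(iou))
        used_p.add(pi)
    return matched


def match_rate(
    truth_labels: np.ndarray,
    pred_labels: np.ndarray,
    truth_ids: np.ndarray,
    min_iou: float = 0.5,
) -> float:
    """Fraction of the given truth ids matched one-to-one at IoU >= min_iou."""
    matched = match_nuclei(truth_labels, pred_labels)
    hits = sum(
        1 for cid in truth_ids if cid in matched and matched[cid][1] >= min_iou
    )
    return hits / len(truth_ids) if len(truth_ids) else float("nan")
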