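"""Task-related vertex selection by split-half representational consistency.

For each vertex, the RDM of the regular images is computed twice within the
vertex's searchlight disk — once from the first presentation's betas, once
from the second — and the two RDMs are compared by Spearman rank
correlation.  The most consistent vertices (top N per hemisphere per ROI,
default 100, i.e. 200 per ROI) are retained.  Selection uses the regular
images only; the adversarial responses play no role.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import DataError
from .rsa import compute_rdm, rdm_similarity, searchlight_disks
from .synth import ResponseDataset


def splithalf_consistency(
    responses: ResponseDataset,
    radius: float = 3.0,
    metric: str = "correlation",
    min_disk: int = 3,
) -> pd.DataFrame:
    """Per-vertex Spearman correlation between the two presentations' RDMs.

    Requires exactly two repetitions.  Disks with fewer than ``min_disk``
    vertices get a missing consistency value.  Returns a frame with columns
    vertex_id, roi, hemisphere, n_disk, consistency.
    """
    re = responses.betas["RE"]
    if re.shape[2] != 2:
        raise DataError(f"split-half consistency needs exactly 2 repetitions, got {re.shape[2]}")
    sheet = responses.sheet
    id_to_row = {int(v): i for i, v in enumerate(sheet.table["vertex_id"].to_numpy())}
    rows = []
    for (vid, roi, hemi), disk in zip(
        sheet.table[["vertex_id", "roi", "hemisphere"]].itertuples(index=False),
        searchlight_disks(sheet, radius),
    ):
        if disk.size < min_disk:
            rows.append((vid, roi, hemi, disk.size, np.nan))
            continue
        sel = [id_to_row[int(v)] for v in disk]
        rdm1 = compute_rdm(re[sel, :, 0].T, metric=metric)  # images x disk vertices
        rdm2 = compute_rdm(re[sel, :, 1].T, metric=metric)
        rows.append((vid, roi, hemi, disk.size, rdm_similarity(rdm1, rdm2)))
    return pd.DataFrame(
        rows, columns=["vertex_id", "roi", "hemisphere", "n_disk", "consistency"]
    )


def select_vertices(
    consistency_map: pd.DataFrame,
    n_per_hemisphere: int = 100,
) -> pd.DataFrame:
    """Top ``n_per_hemisphere`` vertices per (ROI, hemisphere) by consistency.

    Missing-consistency vertices are excluded before ranking; ties are broken
    by ascending vertex_id so selection is deterministic.  Raises a
    :class:`DataError` naming any block with too few rankable vertices.
    """
    valid = consistency_map.dropna(subset=["consistency"])
    out = []
    for (roi, hemi), block in valid.groupby(["roi", "hemisphere"], sort=False):
        if len(block) < n_per_hemisphere:
            raise DataError(
                f"block ({roi}, {hemi}) has {len(block)} rankable vertices, "
                f"need {n_per_hemisphere}"
            )
        ranked = block.sort_values(
            ["consistency", "vertex_id"], ascending=[False, True], kind="mergesort"
        )
        out.append(ranked.head(n_per_hemisphere))
    sel = pd.concat(out, ignore_index=True)
    return sel.sort_values("vertex_id", ignore_index=True)


def selected_ids_by_roi(selection: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        roi: block["vertex_id"].to_numpy()
        for roi, block in selection.groupby("roi", sort=False)
    }
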