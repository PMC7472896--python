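"""Atlas-overlap labelling of cluster masks.

Maps each connected cluster of a binary mask onto a labelled parcellation
and reports, per cluster, how much of it falls within each label (the
remainder being background).  This is the generic stand-in for reporting
clusters against named anatomical atlases.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .synth import ParcellationAtlas
from .volumes import Volume, _structure


def atlas_overlap_report(
    cluster_mask: Volume,
    atlas: ParcellationAtlas | Volume,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Per-cluster overlap fractions with atlas labels.

    Returns a table (cluster_id, label, name, n_overlap_voxels, fraction)
    where fractions within a cluster sum to <= 1; the unassigned remainder
    is reported under label 0 / "background".
    """
    if isinstance(atlas, Volume):
        atlas = ParcellationAtlas(atlas, {})
    if not cluster_mask.same_grid(atlas.labels):
        raise ValueError("cluster mask and atlas grids differ")
    data = np.asarray(cluster_mask.data) > 0
    labels_vol = np.asarray(atlas.labels.data)
    clusters, n = ndimage.label(data, structure=_structure(connectivity))
    rows = []
    for cid in range(1, n + 1):
        sel = clusters == cid
        size = int(sel.sum())
        lab_counts = np.bincount(labels_vol[sel].ravel())
        for lab in np.flatnonzero(lab_counts):
            rows.append(dict(
                cluster_id=cid,
                label=int(lab),
                name=atlas.names.get(int(lab), "background" if lab == 0 else f"label_{lab:02d}"),
                n_overlap_voxels=int(lab_counts[lab]),
                fraction=float(lab_counts[lab] / size),
            ))
    return pd.DataFrame(
        rows, columns=["cluster_id", "label", "name", "n_overlap_voxels", "fraction"]
    )
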