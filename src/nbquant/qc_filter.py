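"""Quality control: exclusion flags and cohort assembly.

Nuclei are excluded for (i) biological or methodological artifacts and
(ii) overlapping cytoplasmic label — both inherently visual judgements, so
they enter as an explicit manual id list.  Two automatic flags (nucleus
touching the stack border; more than a set fraction of saturated voxels)
cover the objectively detectable cases.  Excluded nuclei stay in the table
with ``excluded = True`` for auditability; downstream statistics consume
only the non-excluded rows.  No row is ever dropped silently.

:func:`flag_cytoplasmic` is a reproducible numeric surrogate for the visual
"pronounced cytoplasmic labeling" call.  It compares the median protein
intensity in a thin shell just outside the nucleus with the median inside;
the flag feeds the categorical group comparison only and never triggers an
automatic exclusion.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigurationError, ConsistencyError
from .stack_io import COHORT_COLUMNS

logger = logging.getLogger(__name__)

REASON_NONE = "none"
REASON_ARTIFACT = "artifact_manual"
REASON_CYTOPLASMIC = "cytoplasmic_overlap_manual"
REASON_BORDER = "border_auto"
REASON_SATURATION = "saturation_auto"
VALID_REASONS = (
    REASON_NONE, REASON_ARTIFACT, REASON_CYTOPLASMIC, REASON_BORDER, REASON_SATURATION
)

__all__ = [
    "apply_exclusions",
    "flag_cytoplasmic",
    "REASON_NONE",
    "REASON_ARTIFACT",
    "REASON_CYTOPLASMIC",
    "REASON_BORDER",
    "REASON_SATURATION",
]


def apply_exclusions(
    metrics: Sequence[Mapping],
    manual_list: Optional[Sequence] = None,
    auto_flags: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the cohort table and apply exclusion flags.

    Parameters
    ----------
    metrics
        Per-nucleus dicts with keys source_id, group, n_bodies,
        mean_diameter_um, mean_max_intensity, cytoplasmic_flag.
    manual_list
        Ids to exclude manually; entries are either bare source ids
        (reason defaults to ``artifact_manual``) or ``{"id": ..,
        "reason": ..}`` mappings.  Unknown ids raise
        :class:`ConfigurationError`.
    auto_flags
        Mapping source_id -> reason for automatically flagged nuclei;
        manual reasons take precedence.

    Returns
    -------
    (table, summary)
        The cohort DataFrame (every input row present) and a summary dict
        with total/excluded counts, the percentage excluded rounded to one
        decimal, and counts by reason.
    """
    rows = []
    for m in metrics:
        rows.append(
            {
                "source_id": m["source_id"],
                "group": m["group"],
                "n_bodies": int(m["n_bodies"]),
                "mean_diameter_um": m.get("mean_diameter_um"),
                "mean_max_intensity": m.get("mean_max_intensity"),
                "cytoplasmic_flag": m.get("cytoplasmic_flag"),
                "excluded": False,
                "exclusion_reason": REASON_NONE,
            }
        )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    table["cytoplasmic_flag"] = table["cytoplasmic_flag"].astype("boolean")
    known = set(table["source_id"])

    reasons: dict[str, str] = {}
    for sid, reason in (auto_flags or {}).items():
        if sid not in known:
            raise ConfigurationError(f"auto flag for unknown nucleus id {sid!r}")
        reasons[sid] = reason
    for entry in manual_list or []:
        if isinstance(entry, Mapping):
            sid, reason = entry["id"], entry.get("reason", REASON_ARTIFACT)
        else:
            sid, reason = entry, REASON_ARTIFACT
        if sid not in known:
            raise ConfigurationError(f"manual exclusion references unknown id {sid!r}")
        if reason not in VALID_REASONS or reason == REASON_NONE:
            raise ConfigurationError(f"invalid exclusion reason {reason!r} for {sid!r}")
        reasons[sid] = reason  # manual overrides any auto flag

    if reasons:
        sel = table["source_id"].map(reasons).fillna(REASON_NONE)
        table["exclusion_reason"] = sel
        table["excluded"] = sel != REASON_NONE

    total = len(table)
    excluded = int(table["excluded"].sum())
    summary = {
        "total": total,
        "excluded": excluded,
        "analysis_rows": total - excluded,
        "pct_excluded": round(100.0 * excluded / total, 1) if total else 0.0,
        "by_reason": table.loc[table["excluded"], "exclusion_reason"]
        .value_counts()
        .to_dict(),
    }
    if len(table) != len(metrics):
        raise ConsistencyError("row count changed during exclusion flagging")
    return table, summary


def flag_cytoplasmic(
    protein_crop: np.ndarray,
    nucleus_mask: np.ndarray,
    ratio_threshold: float = 0.5,
    shell_voxels: int = 3,
) -> Optional[bool]:
    """Score cytoplasmic protein labeling around one nucleus.

    True iff the median protein intensity in a ``shell_voxels``-wide shell
    outside the nucleus mask is at least ``ratio_threshold`` times the
    median intensity inside.  Returns ``None`` (flag absent) when the
    nucleus fills the crop and no shell exists; the caller logs this.
    Raising the threshold can only shrink the set of flagged nuclei.
    """
    protein = np.asarray(protein_crop)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if protein.shape != mask.shape:
        raise ConsistencyError("protein crop and nucleus mask differ in shape")
    shell = ndimage.binary_dilation(mask, iterations=shell_voxels) & ~mask
    if not shell.any():
        logger.warning("nucleus fills its crop; cytoplasmic flag is undefined")
        return None
    inside = float(np.median(protein[mask]))
    outside = float(np.median(protein[shell]))
    if inside == 0:
        return outside > 0
    return outside >= ratio_threshold * inside
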