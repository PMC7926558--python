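"""OA-subtracted DHA/EPA signature set algebra and composition summaries.

A gene is *responsive* to a condition when its DE call for that contrast is
up or down. The signature classes partition the DE universe:

* ``DHA_only``     — responsive to DHA, not EPA, not OA
* ``EPA_only``     — responsive to EPA, not DHA, not OA
* ``DHA_and_EPA``  — responsive to both DHA and EPA, not OA
* ``OA_shared``    — responsive to OA and to DHA or EPA (set aside: an
  oleic-acid-shared response is not an omega-3-specific signature)
* ``non_responsive`` — everything else, including OA-only responders

OA subtraction is any-direction: an OA call in either direction excludes a
gene from the signature classes. Genes responsive to DHA and EPA in opposite
directions stay in ``DHA_and_EPA`` but carry a discordance flag.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GeneTable

logger = logging.getLogger("omega3sig")

__all__ = ["SIGNATURE_CLASSES", "assign_signatures", "composition_summary",
           "overlap_with_external_deg", "upset_matrix"]

SIGNATURE_CLASSES = ("DHA_only", "EPA_only", "DHA_and_EPA", "OA_shared",
                     "non_responsive")


def assign_signatures(
    de_results: Mapping[str, pd.DataFrame], genes: GeneTable
) -> pd.DataFrame:
    """Classify every universe gene from its three DE calls.

    ``de_results`` maps condition name (DHA, EPA, OA) to a called DE frame
    indexed by gene_id; all three contrasts must cover every gene.
    Returns a frame with per-contrast direction columns, the signature class
    and the DHA/EPA direction-discordance flag.
    """
    required = {"DHA", "EPA", "OA"}
    if set(de_results) != required:
        raise ValueError(f"need exactly the contrasts {sorted(required)}, "
                         f"got {sorted(de_results)}")
    idx = de_results["DHA"].index
    for cond in ("EPA", "OA"):
        if not de_results[cond].index.equals(idx):
            diff = idx.symmetric_difference(de_results[cond].index)
            raise ValueError(
                f"contrast {cond} does not cover the same universe "
                f"(e.g. {diff[:3].tolist()})")

    calls = pd.DataFrame({f"call_{c}": de_results[c]["call"] for c in
                          ("DHA", "EPA", "OA")}, index=idx)
    resp = {c: (calls[f"call_{c}"] != "ns").to_numpy() for c in ("DHA", "EPA", "OA")}

    cls = np.full(len(idx), "non_responsive", dtype=object)
    oa_shared = resp["OA"] & (resp["DHA"] | resp["EPA"])
    cls[resp["DHA"] & ~resp["EPA"] & ~resp["OA"]] = "DHA_only"
    cls[~resp["DHA"] & resp["EPA"] & ~resp["OA"]] = "EPA_only"
    cls[resp["DHA"] & resp["EPA"] & ~resp["OA"]] = "DHA_and_EPA"
    cls[oa_shared] = "OA_shared"

    discordant = (
        resp["DHA"] & resp["EPA"]
        & (calls["call_DHA"].to_numpy() != calls["call_EPA"].to_numpy())
    )
    out = calls.copy()
    out["biotype"] = genes.biotype_of(idx).to_numpy()
    out["signature_class"] = cls
    out["discordant"] = discordant
    n = out["signature_class"].value_counts()
    logger.info("signature classes: %s", n.to_dict())
    return out


def composition_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per (class, biotype, DHA/EPA direction).

    The direction of a signature gene is its DHA call when DHA-responsive,
    else its EPA call. Fractions are within each (class, biotype) margin and
    sum to 1 there.
    """
    if assignments.empty:
        raise ValueError("empty assignment table")
    a = assignments.copy()
    direction = np.where(a["call_DHA"] != "ns", a["call_DHA"], a["call_EPA"])
    a["direction"] = np.where(direction == "ns", "none", direction)
    rows = []
    for (cls, biotype), grp in a.groupby(["signature_class", "biotype"],
                                         sort=True, observed=True):
        total = len(grp)
        for dirn, sub in grp.groupby("direction", sort=True):
            rows.append({"signature_class": cls, "biotype": biotype,
                         "direction": dirn, "count": len(sub),
                         "fraction": len(sub) / total})
    return pd.DataFrame(rows)


def overlap_with_external_deg(
    assignments: pd.DataFrame, external_deg: set[str] | list[str]
) -> pd.DataFrame:
    """Per-class overlap with an external DE gene set (e.g. a disease cohort).

    External genes outside the universe are intersected away with a warning;
    an empty external set warns and yields zero overlaps.
    """
    external = set(external_deg)
    if not external:
        logger.warning("external DE set is empty; overlaps are all zero")
    universe = set(assignments.index)
    outside = external - universe
    if outside:
        logger.warning("%d external gene(s) outside the universe ignored", len(outside))
        external &= universe
    rows = []
    for cls in SIGNATURE_CLASSES:
        members = set(assignments.index[assignments["signature_class"] == cls])
        inter = members & external
        rows.append({
            "signature_class": cls,
            "class_size": len(members),
            "overlap": len(inter),
            "fraction_of_class": len(inter) / len(members) if members else 0.0,
            "fraction_of_external": len(inter) / len(external) if external else 0.0,
        })
    return pd.DataFrame(rows)


def upset_matrix(assignments: pd.DataFrame) -> pd.DataFrame:
    """UpSet-style intersection table: binary membership columns + count."""
    a = assignments
    memb = pd.DataFrame({
        c: (a[f"call_{c}"] != "ns").astype(int) for c in ("DHA", "EPA", "OA")
    }, index=a.index)
    out = memb.groupby(["DHA", "EPA", "OA"]).size().rename("count").reset_index()
    return out.sort_values("count", ascending=False).reset_index(drop=True)
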