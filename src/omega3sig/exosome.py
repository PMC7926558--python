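"""Exosomal read-origin partitioning and the top-20% detectability filter.

Exosomal RNA from a liver-humanized mouse is mapped against a combined
human+mouse reference whose contigs carry ``human_`` / ``mouse_`` prefixes.
A read is assigned to the genome on which its best-scoring alignments fall
exclusively; equal best scores on both genomes make it ambiguous, and
ambiguous reads are excluded downstream (only human-*specific* reads are
informative about the humanized liver). Human-assigned reads are summarised
per human gene (multi-gene reads split fractionally), genes are ranked by
raw read count, and the top fraction (default 20%) is flagged detectable —
the accessible-biomarker candidates, finally intersected with the
most-variable signature genes per class.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import GeneTable

logger = logging.getLogger("omega3sig")

__all__ = ["assign_origin", "quantify_human_genes", "top_fraction",
           "biomarker_intersection", "read_alignment_tsv", "read_alignment_sam"]

PREFIXES = {"human_": "human", "mouse_": "mouse"}


def _origin_of_contig(contig: str) -> str:
    for prefix, origin in PREFIXES.items():
        if contig.startswith(prefix):
            return origin
    raise ValueError(f"contig {contig!r} lacks a known species prefix")


def assign_origin(records: pd.DataFrame) -> pd.DataFrame:
    """Per-read origin from best-scoring alignments on the combined reference.

    ``records`` needs columns read_id, contig, gene_id, score. A read is
    human iff every best-scoring alignment lies on human contigs (mouse
    analogously); best scores on both genomes make it ambiguous. Returns a
    per-read frame with the origin and, for unambiguous reads, the list of
    best-scoring genes on the winning genome.
    """
    if records.empty:
        return pd.DataFrame(columns=["read_id", "origin", "genes"])
    df = records.copy()
    df["origin_raw"] = df["contig"].map(_origin_of_contig)
    best = df.groupby("read_id")["score"].transform("max")
    top = df[df["score"] == best]
    rows = []
    for read_id, grp in top.groupby("read_id", sort=True):
        origins = set(grp["origin_raw"])
        if len(origins) > 1:
            rows.append((read_id, "ambiguous", ()))
        else:
            origin = origins.pop()
            genes = tuple(sorted(set(grp["gene_id"])))
            rows.append((read_id, origin, genes))
    out = pd.DataFrame(rows, columns=["read_id", "origin", "genes"])
    tally = out["origin"].value_counts()
    logger.info("origin tally: %s (total %d reads)", tally.to_dict(), len(out))
    assert tally.sum() == out["read_id"].nunique()
    return out


def quantify_human_genes(
    origins: pd.DataFrame, gene_table: GeneTable
) -> pd.Series:
    """Human-specific read count per human gene.

    A read hitting n genes at its best score contributes 1/n to each
    (conservation-preserving); reads on genes absent from the table are
    counted in an ``__unassigned__`` bucket with a warning.
    """
    human_genes = set(gene_table.genes_of_species("human"))
    counts: dict[str, float] = {}
    unassigned = 0.0
    for genes in origins.loc[origins["origin"] == "human", "genes"]:
        w = 1.0 / len(genes)
        for g in genes:
            if g in human_genes:
                counts[g] = counts.get(g, 0.0) + w
            else:
                unassigned += w
    if unassigned:
        logger.warning("%.1f read(s) on genes absent from the gene table", unassigned)
        counts["__unassigned__"] = unassigned
    return pd.Series(counts, name="reads", dtype=float).sort_index()


def top_fraction(counts: pd.Series, frac: float) -> list[str]:
    """Genes in the top ``frac`` by read count: the detectable set.

    Exactly ceil(frac * n) genes; ranking is by count descending with
    boundary ties broken by ascending gene_id.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {frac}")
    counts = counts.drop(index="__unassigned__", errors="ignore")
    if counts.empty:
        return []
    n_top = math.ceil(frac * len(counts))
    ordered = counts.to_frame("reads").reset_index()
    idcol = ordered.columns[0]
    ordered = ordered.sort_values(["reads", idcol], ascending=[False, True])
    return ordered[idcol].head(n_top).tolist()


def biomarker_intersection(
    detectable: Sequence[str],
    most_variable_signatures: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Exosome-detectable members of each most-variable signature class."""
    det = set(detectable)
    rows = []
    for cls, members in most_variable_signatures.items():
        inter = sorted(set(members) & det)
        rows.append({"signature_class": cls, "n_signature": len(set(members)),
                     "n_detected": len(inter), "detected_genes": ",".join(inter)})
    return pd.DataFrame(rows)


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    """Simplified alignment table: read_id, contig, gene_id, score."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str,
                                            "gene_id": str})
    missing = {"read_id", "contig", "gene_id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing column(s): {sorted(missing)}")
    return df


def read_alignment_sam(path: str | Path) -> pd.DataFrame:
    """Map SAM records to alignment rows via reference-name prefixes.

    Follows the simulated post-mapping convention that each reference
    sequence is one gene's transcript, named ``<prefix><gene_id>``; primary
    and secondary alignments are both included. Alignment score is taken
    from the AS tag, falling back to mapping quality.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            contig = aln.reference_name
            origin = _origin_of_contig(contig)  # validates the prefix
            gene_id = contig.split("_", 1)[1]
            score = float(aln.get_tag("AS")) if aln.has_tag("AS") \
                else float(aln.mapping_quality)
            rows.append((aln.query_name, contig, gene_id, score, origin))
    return pd.DataFrame(rows, columns=["read_id", "contig", "gene_id",
                                       "score", "origin"]).drop(columns="origin")
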