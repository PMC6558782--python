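"""Anchoring scaffolds to the genetic map and building pseudomolecules.

Markers are located on scaffolds by exact flank matching (an import path
accepts precomputed tabular alignments for real data); markers hitting more
than one scaffold are discarded.  Each scaffold is then assigned to the
linkage group holding the majority of its mapped markers, scaffolds are
ordered within a chromosome by the mean cM of their markers, and oriented by
comparing the physical (bp) and genetic (cM) marker orders: if concordant
pairs outnumber discordant ones the scaffold is '+', if fewer '−', and a
scaffold whose orientation cannot be decided stays '+' by default.
Pseudomolecules are concatenations of the ordered, oriented scaffolds with
an N-gap spacer, described by an AGP v2.1 plan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkmap import GeneticMap
from .util import atomic_write, revcomp

log = logging.getLogger(__name__)

PLACEMENT_COLUMNS = [
    "scaffold",
    "chromosome",
    "rank",
    "orientation",
    "orientation_known",
    "mean_cM",
    "n_markers",
    "length",
    "offset",
]


# ---------------------------------------------------------------------------
# Marker placement on scaffolds
# ---------------------------------------------------------------------------

def _concat_index(scaffolds: dict[str, str]):
    names = sorted(scaffolds)
    lengths = np.array([len(scaffolds[n]) for n in names])
    starts = np.concatenate([[0], np.cumsum(lengths + 1)[:-1]])  # +1 for '#'
    blob = "#".join(scaffolds[n] for n in names)
    return blob, names, starts, lengths


def place_markers(
    flanks: dict[str, str],
    scaffolds: dict[str, str],
    min_flank: int = 21,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-match placement of marker flanks (both strands) on scaffolds.

    The SNP base is assumed centered in its flank; the reported position is
    the SNP base, 1-based.  Markers with zero hits, hits on two or more
    scaffolds, or two or more hits on one scaffold are rejected with a
    reason; flanks shorter than ``min_flank`` are skipped with a warning.

    Returns (placements[marker, scaffold, position, strand],
    rejected[marker, reason]).
    """
    blob, names, starts, lengths = _concat_index(scaffolds)
    placed, rejected = [], []
    for marker in sorted(flanks):
        flank = flanks[marker].upper()
        if len(flank) < min_flank:
            log.warning("marker %s: flank shorter than %d bp, skipped", marker, min_flank)
            rejected.append((marker, "flank_too_short"))
            continue
        center = len(flank) // 2
        hits = []
        for strand, query in (("+", flank), ("-", revcomp(flank))):
            for p in _find_all(blob, query):
                si = int(np.searchsorted(starts, p, side="right") - 1)
                local = p - starts[si]  # 0-based within scaffold
                snp0 = local + (center if strand == "+" else len(flank) - 1 - center)
                hits.append((names[si], int(snp0) + 1, strand))
        if not hits:
            rejected.append((marker, "no_hit"))
        elif len({h[0] for h in hits}) > 1:
            rejected.append((marker, "multiple_scaffolds"))
        elif len(hits) > 1:
            rejected.append((marker, "multiple_sites"))
        else:
            placed.append((marker, *hits[0]))
    placements = pd.DataFrame(placed, columns=["marker", "scaffold", "position", "strand"])
    rejects = pd.DataFrame(rejected, columns=["marker", "reason"])
    if len(rejects):
        log.info("place_markers: %d markers rejected (%s)",
                 len(rejects), rejects["reason"].value_counts().to_dict())
    return placements, rejects


def _find_all(blob: str, query: str):
    i = blob.find(query)
    while i != -1:
        yield i
        i = blob.find(query, i + 1)


# ---------------------------------------------------------------------------
# Scaffold assignment, ordering, orientation
# ---------------------------------------------------------------------------

def assign_scaffolds(
    marker_scaffolds: pd.DataFrame, genetic_map: GeneticMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each scaffold to the linkage group of the majority of its
    mapped markers; a tie (or no mapped marker) leaves it unassigned.

    ``marker_scaffolds`` needs columns marker, scaffold, position.  Returns
    (table[marker, scaffold, position, group, position_cM] restricted to
    scaffolds with a winning group, unassigned[scaffold, reason]).
    """
    mapped = marker_scaffolds.merge(genetic_map.positions, on="marker", how="inner")
    with_markers = set(marker_scaffolds["scaffold"])
    winners = {}
    unassigned = []
    for scaffold, grp in mapped.groupby("scaffold"):
        counts = grp["group"].value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            unassigned.append((scaffold, "tie"))
        else:
            winners[scaffold] = counts.index[0]
    for scaffold in sorted(with_markers - set(winners) - {s for s, _ in unassigned}):
        unassigned.append((scaffold, "no_mapped_marker"))
    keep = mapped[
        mapped.apply(lambda r: winners.get(r["scaffold"]) == r["group"], axis=1)
    ].reset_index(drop=True)
    return keep, pd.DataFrame(sorted(unassigned), columns=["scaffold", "reason"])


def orient_scaffold(bp_positions, cm_positions) -> tuple[str, bool]:
    """Orientation from pairwise order concordance of bp vs cM positions.

    Counts marker pairs whose physical and genetic orders agree (concordant)
    or oppose (discordant); pairs tied in either coordinate are ignored.
    More concordant → ('+', known); more discordant → ('−', known); equal
    counts (including no usable pair at all, e.g. a single marker) →
    ('+', unknown) — the positive-by-default convention.
    """
    bp = np.asarray(bp_positions, dtype=float)
    cm = np.asarray(cm_positions, dtype=float)
    if bp.size == 0:
        raise ValueError("scaffold has no mapped markers")
    conc = disc = usable = 0
    for i in range(bp.size):
        for j in range(i + 1, bp.size):
            db, dc = bp[j] - bp[i], cm[j] - cm[i]
            if db == 0 or dc == 0:
                continue
            usable += 1
            if (db > 0) == (dc > 0):
                conc += 1
            else:
                disc += 1
    if conc == disc:
        return "+", False
    return ("+" if conc > disc else "-"), True


def order_scaffolds(
    assigned: pd.DataFrame, scaffold_lengths: dict[str, int]
) -> pd.DataFrame:
    """Rank scaffolds within each chromosome by mean marker cM and orient them.

    ``assigned`` is the per-marker table from :func:`assign_scaffolds`.
    Ties in mean cM break lexicographically by scaffold id.  Returns a
    placement table (offset not yet filled).
    """
    rows = []
    for (group, scaffold), grp in assigned.groupby(["group", "scaffold"]):
        orientation, known = orient_scaffold(grp["position"].to_numpy(), grp["position_cM"].to_numpy())
        rows.append(
            (
                scaffold,
                group,
                float(grp["position_cM"].mean()),
                orientation,
                known,
                len(grp),
            )
        )
    df = pd.DataFrame(
        rows, columns=["scaffold", "chromosome", "mean_cM", "orientation", "orientation_known", "n_markers"]
    )
    df = df.sort_values(["chromosome", "mean_cM", "scaffold"], kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("chromosome").cumcount() + 1
    df["length"] = df["scaffold"].map(scaffold_lengths)
    df["offset"] = pd.NA
    return df[PLACEMENT_COLUMNS]


# ---------------------------------------------------------------------------
# Pseudomolecule assembly and AGP
# ---------------------------------------------------------------------------

AGP_COLUMNS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]


def build_pseudomolecules(
    scaffolds: dict[str, str],
    placements: pd.DataFrame,
    gap_bp: int = 100,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Concatenate ordered, oriented scaffolds into chromosome sequences.

    Scaffolds oriented '−' are reverse-complemented; ``gap_bp`` N characters
    separate consecutive scaffolds.  Returns (chromosome sequences, AGP v2.1
    table, placements with 1-based ``offset`` filled in).
    """
    if placements["scaffold"].duplicated().any():
        dup = placements.loc[placements["scaffold"].duplicated(), "scaffold"].iloc[0]
        raise ValueError(f"scaffold {dup} appears more than once in placements")
    chrom_seqs: dict[str, str] = {}
    agp_rows = []
    placements = placements.sort_values(["chromosome", "rank"], kind="mergesort").copy()
    offsets = []
    for chrom, grp in placements.groupby("chromosome", sort=True):
        parts = []
        pos = 1
        part_no = 0
        for i, row in enumerate(grp.itertuples(index=False)):
            if i > 0 and gap_bp > 0:
                part_no += 1
                agp_rows.append(
                    (chrom, pos, pos + gap_bp - 1, part_no, "U", gap_bp, "scaffold", "yes", "map")
                )
                parts.append("N" * gap_bp)
                pos += gap_bp
            seq = scaffolds[row.scaffold]
            if row.orientation == "-":
                seq = revcomp(seq)
            part_no += 1
            agp_rows.append(
                (chrom, pos, pos + len(seq) - 1, part_no, "W", row.scaffold, 1, len(seq), row.orientation)
            )
            offsets.append((row.scaffold, pos))
            parts.append(seq)
            pos += len(seq)
        chrom_seqs[chrom] = "".join(parts)
    agp = pd.DataFrame(agp_rows, columns=AGP_COLUMNS)
    offset_map = dict(offsets)
    placements["offset"] = placements["scaffold"].map(offset_map)
    return chrom_seqs, agp, placements.reset_index(drop=True)


def write_agp(agp: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", index=False, header=False)


def read_agp(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=AGP_COLUMNS)
    return df


def write_placements(placements: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with atomic_write(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        placements.to_csv(fh, sep="\t", index=False)


def read_placements(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
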