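"""Feature placement on scaffolds and coordinate liftover onto chromosomes.

Transcripts are located by exact substring search on both strands (spliced
alignment is out of scope; an import path accepts external alignment
intervals for real data).  SSR loci are found by in-silico PCR: both primers
must match exactly on the same strand with an outer-end-to-outer-end
amplicon strictly shorter than 400 bp.  SNPs arrive with scaffold
coordinates from the genotype table.  Anchored scaffold coordinates are then
transformed through the scaffold placements:

    orientation '+':  [s, e] -> [O + s − 1, O + e − 1], strand kept
    orientation '−':  [s, e] -> [O + L − e, O + L − s], strand flipped

with O the scaffold's 1-based chromosome offset and L its length.
"""

from __future__ import annotations

import logging

import pandas as pd

from .segpattern import GenotypeMatrix
from .util import atomic_write, find_all, revcomp

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "feature",
    "kind",
    "scaffold",
    "start",
    "end",
    "strand",
    "status",
    "chromosome",
    "chrom_start",
    "chrom_end",
    "chrom_strand",
    "anchored",
]


# ---------------------------------------------------------------------------
# Transcript placement
# ---------------------------------------------------------------------------

def map_transcript(
    name: str, seq: str, scaffolds: dict[str, str], min_length: int = 100
) -> tuple:
    """Exact-match placement of one transcript; returns a feature row.

    Unique hit → (scaffold interval, strand, 'unique'); several hits → the
    first by (scaffold, position) flagged 'ambiguous'; none → 'unmapped'.
    """
    if len(seq) < min_length:
        return (name, "transcript", None, None, None, None, "too_short")
    hits = []
    for sid in sorted(scaffolds):
        s = scaffolds[sid]
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for p in find_all(s, query):
                hits.append((sid, p + 1, p + len(seq), strand))
    if not hits:
        return (name, "transcript", None, None, None, None, "unmapped")
    hits.sort()
    sid, start, end, strand = hits[0]
    status = "unique" if len(hits) == 1 else "ambiguous"
    return (name, "transcript", sid, start, end, strand, status)


def map_transcripts(transcripts: dict[str, str], scaffolds: dict[str, str]) -> pd.DataFrame:
    rows = [map_transcript(n, transcripts[n], scaffolds) for n in sorted(transcripts)]
    return pd.DataFrame(
        rows, columns=["feature", "kind", "scaffold", "start", "end", "strand", "status"]
    )


def import_alignments(path) -> pd.DataFrame:
    """Read precomputed feature-to-scaffold alignments.

    Tab-separated columns: feature, scaffold, start, end, strand (1-based
    inclusive).  Use this in place of the exact mapper for real spliced
    aligner output.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["feature", "scaffold", "start", "end", "strand"], header=0,
    )
    df.insert(1, "kind", "transcript")
    df["status"] = "unique"
    return df


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _validate_primer(name: str, seq: str) -> str:
    seq = seq.strip().upper()
    if not (15 <= len(seq) <= 30) or set(seq) - set("ACGT"):
        raise ValueError(f"{name} primer must be 15-30 bp of ACGT, got {seq!r}")
    return seq


def epcr_locate(
    forward: str, reverse: str, scaffolds: dict[str, str], max_amplicon: int = 400
) -> pd.DataFrame:
    """All loci where the primer pair amplifies a product < ``max_amplicon`` bp.

    On strand '+' the forward primer matches the scaffold and the reverse
    complement of the reverse primer lies downstream; on strand '−' the
    roles are mirrored.  The amplicon is measured outer end to outer end and
    the bound is strict.  Loci are sorted by (scaffold, start).
    """
    fwd = _validate_primer("forward", forward)
    rev = _validate_primer("reverse", reverse)
    rows = []
    for sid in sorted(scaffolds):
        seq = scaffolds[sid]
        # strand +: fwd at s (1-based), revcomp(rev) ends at e
        f_starts = [p + 1 for p in find_all(seq, fwd)]
        r_ends = [p + len(rev) for p in find_all(seq, revcomp(rev))]
        for s in f_starts:
            for e in r_ends:
                if e > s and e - s + 1 < max_amplicon:
                    rows.append((sid, s, e, "+"))
        # strand -: rev at s on the plus strand, revcomp(fwd) ends at e
        r_starts = [p + 1 for p in find_all(seq, rev)]
        f_ends = [p + len(fwd) for p in find_all(seq, revcomp(fwd))]
        for s in r_starts:
            for e in f_ends:
                if e > s and e - s + 1 < max_amplicon:
                    rows.append((sid, s, e, "-"))
    out = pd.DataFrame(rows, columns=["scaffold", "start", "end", "strand"])
    return out.drop_duplicates().sort_values(["scaffold", "start", "end"]).reset_index(drop=True)


def locate_ssrs(
    primers: pd.DataFrame, scaffolds: dict[str, str], max_amplicon: int = 400
) -> pd.DataFrame:
    """e-PCR every primer pair; one feature row per SSR.

    Multi-locus pairs keep the first locus by coordinate and are flagged
    'ambiguous' so category counts stay deterministic.
    """
    rows = []
    for row in primers.itertuples(index=False):
        loci = epcr_locate(row.forward, row.reverse, scaffolds, max_amplicon)
        if loci.empty:
            rows.append((row.ssr, "ssr", None, None, None, None, "unmapped"))
        else:
            first = loci.iloc[0]
            status = "unique" if len(loci) == 1 else "ambiguous"
            rows.append(
                (row.ssr, "ssr", first["scaffold"], int(first["start"]), int(first["end"]),
                 first["strand"], status)
            )
    return pd.DataFrame(
        rows, columns=["feature", "kind", "scaffold", "start", "end", "strand", "status"]
    )


def snp_intervals(matrix: GenotypeMatrix) -> pd.DataFrame:
    """SNP feature rows (start = end = position) from a genotype table."""
    mk = matrix.markers
    return pd.DataFrame(
        {
            "feature": mk["marker"],
            "kind": "snp",
            "scaffold": mk["scaffold"],
            "start": mk["position"],
            "end": mk["position"],
            "strand": ".",
            "status": "unique",
        }
    )


# ---------------------------------------------------------------------------
# Coordinate liftover
# ---------------------------------------------------------------------------

_FLIP = {"+": "-", "-": "+", ".": "."}


def lift_interval(
    start: int, end: int, strand: str, orientation: str, offset: int, scaffold_length: int
) -> tuple[int, int, str]:
    """Scaffold interval -> chromosome interval through one placement."""
    if not (1 <= start <= end <= scaffold_length):
        raise ValueError(f"interval [{start}, {end}] outside scaffold of length {scaffold_length}")
    if orientation == "+":
        return offset + start - 1, offset + end - 1, strand
    return offset + scaffold_length - end, offset + scaffold_length - start, _FLIP[strand]


def inverse_lift_interval(
    chrom_start: int, chrom_end: int, strand: str, orientation: str, offset: int, scaffold_length: int
) -> tuple[int, int, str]:
    """Chromosome interval -> scaffold interval (inverse of lift_interval)."""
    if orientation == "+":
        return chrom_start - offset + 1, chrom_end - offset + 1, strand
    return (
        offset + scaffold_length - chrom_end,
        offset + scaffold_length - chrom_start,
        _FLIP[strand],
    )


def lift_features(features: pd.DataFrame, placements: pd.DataFrame) -> pd.DataFrame:
    """Add chromosome coordinates to every feature on a placed scaffold.

    Features on unplaced scaffolds (or unmapped features) keep empty
    chromosome fields with ``anchored=False``.
    """
    pl = placements.set_index("scaffold")
    out = features.copy()
    chrom, cs, ce, cstr, anchored = [], [], [], [], []
    for row in out.itertuples(index=False):
        if row.scaffold is None or pd.isna(row.scaffold) or row.scaffold not in pl.index:
            chrom.append(None); cs.append(pd.NA); ce.append(pd.NA); cstr.append(None)
            anchored.append(False)
            continue
        p = pl.loc[row.scaffold]
        a, b, s = lift_interval(
            int(row.start), int(row.end), row.strand, p["orientation"], int(p["offset"]), int(p["length"])
        )
        chrom.append(p["chromosome"]); cs.append(a); ce.append(b); cstr.append(s)
        anchored.append(True)
    out["chromosome"] = chrom
    out["chrom_start"] = pd.array(cs, dtype="Int64")
    out["chrom_end"] = pd.array(ce, dtype="Int64")
    out["chrom_strand"] = cstr
    out["anchored"] = anchored
    return out


def integrate_features(
    transcript_hits: pd.DataFrame,
    snp_hits: pd.DataFrame,
    ssr_hits: pd.DataFrame,
    placements: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """One lifted table for all feature kinds, plus per-kind category counts.

    Counts per kind: ``total``, ``mapped`` (placed on some scaffold),
    ``anchored`` (scaffold itself placed on a chromosome), ``ambiguous``.
    """
    frames = [df for df in (transcript_hits, snp_hits, ssr_hits) if len(df)]
    if not frames:
        empty = pd.DataFrame(columns=FEATURE_COLUMNS)
        return empty, {}
    features = pd.concat(frames, ignore_index=True)
    lifted = lift_features(features, placements)
    counts = {}
    for kind, grp in lifted.groupby("kind"):
        counts[kind] = {
            "total": len(grp),
            "mapped": int(grp["scaffold"].notna().sum()),
            "anchored": int(grp["anchored"].sum()),
            "ambiguous": int((grp["status"] == "ambiguous").sum()),
        }
    return lifted[FEATURE_COLUMNS], counts


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_features_tsv(features: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with atomic_write(path) as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        features.to_csv(fh, sep="\t", index=False)


def write_gff3(features: pd.DataFrame, path) -> None:
    """Anchored features in chromosome coordinates as GFF3."""
    types = {"transcript": "mRNA", "snp": "SNV", "ssr": "microsatellite"}
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        anchored = features[features["anchored"]]
        for row in anchored.itertuples(index=False):
            strand = row.chrom_strand if row.chrom_strand in ("+", "-") else "."
            fh.write(
                f"{row.chromosome}\tmapanchor\t{types.get(row.kind, row.kind)}\t"
                f"{row.chrom_start}\t{row.chrom_end}\t.\t{strand}\t.\tID={row.feature}\n"
            )


def write_bed(features: pd.DataFrame, path) -> None:
    """Anchored features as BED (0-based half-open) for track use."""
    with atomic_write(path) as fh:
        anchored = features[features["anchored"]]
        for row in anchored.itertuples(index=False):
            strand = row.chrom_strand if row.chrom_strand in ("+", "-") else "."
            fh.write(
                f"{row.chromosome}\t{int(row.chrom_start) - 1}\t{int(row.chrom_end)}\t"
                f"{row.feature}\t0\t{strand}\n"
            )
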