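"""Per-chromosome resource summaries, totals, percentages, density tracks.

Display arithmetic follows the conventions of the published summary tables
this report emulates: chromosome lengths are shown in Mb rounded half away
from zero at one decimal; transcript densities per Mb are computed from the
*displayed* Mb value; and percentages are computed to two decimals and then
floored at one decimal (so 89.7499% prints as 89.7, not 89.8).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .util import ConfigurationError, atomic_write

SUMMARY_COLUMNS = [
    "chromosome",
    "length_mb",
    "n_transcripts",
    "n_snps",
    "n_ssrs",
    "transcript_density_per_mb",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (decimal display rounding, not banker's)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(numerator: float, denominator: float) -> float:
    """Display percentage: compute to 2 decimals, then floor at 1 decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    p2 = round_half_away(100.0 * numerator / denominator, 2)
    return math.floor(p2 * 10 + 1e-9) / 10


def density_per_mb(count: int, length_mb_displayed: float) -> float:
    """Features per Mb from the displayed (1-decimal) Mb value, 1 decimal."""
    if length_mb_displayed <= 0:
        raise ValueError("chromosome length must be positive")
    return round_half_away(count / length_mb_displayed, 1)


def summarize_counts(
    rows: pd.DataFrame,
    totals_in_genome: dict[str, int],
    mapped_in_genome: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Summary from precomputed per-chromosome counts.

    ``rows`` needs columns chromosome, length_mb, n_transcripts, n_snps,
    n_ssrs (length_mb as displayed, 1 decimal).  ``totals_in_genome`` gives
    the denominators {transcripts, snps, ssrs}; ``mapped_in_genome``
    optionally gives genome-mapped counts for the mapped percentages.

    Returns (per-chromosome table with densities, totals, percentages).
    """
    need = {"chromosome", "length_mb", "n_transcripts", "n_snps", "n_ssrs"}
    if not need <= set(rows.columns):
        raise ValueError(f"rows missing columns {sorted(need - set(rows.columns))}")
    if (rows["length_mb"] <= 0).any():
        raise ValueError("zero-length chromosome in summary rows")
    table = rows.copy()
    table["transcript_density_per_mb"] = [
        density_per_mb(int(r.n_transcripts), float(r.length_mb)) for r in rows.itertuples(index=False)
    ]
    totals = {
        "length_mb": round_half_away(float(rows["length_mb"].sum()), 1),
        "n_transcripts": int(rows["n_transcripts"].sum()),
        "n_snps": int(rows["n_snps"].sum()),
        "n_ssrs": int(rows["n_ssrs"].sum()),
    }
    percentages = {}
    for kind, col in (("transcripts", "n_transcripts"), ("snps", "n_snps"), ("ssrs", "n_ssrs")):
        denom = totals_in_genome.get(kind, 0)
        if denom > 0:
            percentages[f"pct_{kind}_anchored"] = percent(totals[col], denom)
            if mapped_in_genome and kind in mapped_in_genome:
                percentages[f"pct_{kind}_mapped"] = percent(mapped_in_genome[kind], denom)
    return table[SUMMARY_COLUMNS], totals, percentages


def summarize(
    features: pd.DataFrame,
    chromosome_lengths_bp: dict[str, int],
    totals_in_genome: dict[str, int],
) -> tuple[pd.DataFrame, dict, dict]:
    """Summary from an integrated feature table (liftover output).

    Counts anchored features per chromosome and kind; genome-mapped counts
    (denominator-independent) come from the same table.
    """
    for chrom, length in chromosome_lengths_bp.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
    anchored = features[features["anchored"]]
    kinds = {"transcript": "n_transcripts", "snp": "n_snps", "ssr": "n_ssrs"}
    rows = []
    for chrom in sorted(chromosome_lengths_bp):
        grp = anchored[anchored["chromosome"] == chrom]
        counts = {col: int((grp["kind"] == kind).sum()) for kind, col in kinds.items()}
        rows.append(
            {
                "chromosome": chrom,
                "length_mb": round_half_away(chromosome_lengths_bp[chrom] / 1e6, 1),
                **counts,
            }
        )
    mapped = {
        {"transcript": "transcripts", "snp": "snps", "ssr": "ssrs"}[kind]: int(
            (features["kind"] == kind).sum() - (features[features["kind"] == kind]["scaffold"].isna().sum())
        )
        for kind in kinds
    }
    return summarize_counts(pd.DataFrame(rows), totals_in_genome, mapped_in_genome=mapped)


def export_density_tracks(
    features: pd.DataFrame,
    chromosome_lengths_bp: dict[str, int],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Windowed feature counts per chromosome and kind (0-based half-open).

    Transcript tracks are split by chromosome strand (plus/minus); a feature
    is counted in the window containing its anchored start position; the
    last window of each chromosome is truncated to the chromosome end.
    """
    if window_bp <= 0:
        raise ConfigurationError(f"window_bp must be positive, got {window_bp}")
    anchored = features[features["anchored"]]
    rows = []
    for chrom in sorted(chromosome_lengths_bp):
        length = chromosome_lengths_bp[chrom]
        n_win = max(1, math.ceil(length / window_bp))
        edges = [(w * window_bp, min((w + 1) * window_bp, length)) for w in range(n_win)]
        grp = anchored[anchored["chromosome"] == chrom]
        tracks = {
            "transcript_plus": grp[(grp["kind"] == "transcript") & (grp["chrom_strand"] == "+")],
            "transcript_minus": grp[(grp["kind"] == "transcript") & (grp["chrom_strand"] == "-")],
            "snp": grp[grp["kind"] == "snp"],
            "ssr": grp[grp["kind"] == "ssr"],
        }
        for track, sub in tracks.items():
            if len(sub):
                win = ((sub["chrom_start"].astype(int) - 1) // window_bp).to_numpy()
                counts = np.bincount(win, minlength=n_win)
            else:
                counts = np.zeros(n_win, dtype=int)
            for w, (a, b) in enumerate(edges):
                rows.append((chrom, a, b, track, int(counts[w])))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "track", "count"])


def write_summary_tsv(table: pd.DataFrame, totals: dict, percentages: dict, path) -> None:
    with atomic_write(path) as fh:
        table.to_csv(fh, sep="\t", index=False)
        fh.write(
            "total\t{length_mb}\t{n_transcripts}\t{n_snps}\t{n_ssrs}\t-\n".format(**totals)
        )
        for k, v in sorted(percentages.items()):
            fh.write(f"# {k}={v}\n")


def write_summary_text(table: pd.DataFrame, totals: dict, percentages: dict, path) -> None:
    """Aligned, human-readable summary."""
    with atomic_write(path) as fh:
        hdr = f"{'chromosome':<12}{'Mb':>8}{'transcripts':>13}{'SNPs':>9}{'SSRs':>7}{'tx/Mb':>8}"
        fh.write(hdr + "\n")
        for r in table.itertuples(index=False):
            fh.write(
                f"{r.chromosome:<12}{r.length_mb:>8.1f}{r.n_transcripts:>13}"
                f"{r.n_snps:>9}{r.n_ssrs:>7}{r.transcript_density_per_mb:>8.1f}\n"
            )
        fh.write(
            f"{'total':<12}{totals['length_mb']:>8.1f}{totals['n_transcripts']:>13}"
            f"{totals['n_snps']:>9}{totals['n_ssrs']:>7}\n"
        )
        for k, v in sorted(percentages.items()):
            fh.write(f"{k}: {v}%\n")


def write_density_tracks(tracks: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        tracks.to_csv(fh, sep="\t", index=False)
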