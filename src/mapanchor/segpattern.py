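"""Segregation-pattern classification and marker filtering for an F2 cross.

The two parents of the mapping population are heterozygous outbred
individuals, so a SNP locus can show any of the eight CP-model parental
configurations (aa×bb, lm×ll, nn×np, hk×hk, ef×eg, ab×cd, ab×cc, cc×ab).
Only fully informative aa×bb markers — the parents homozygous for different
alleles — segregate 1:2:1 in the F2 and enter the linkage map.  The filter
chain applied here retains a marker iff

* its parental configuration is aa×bb,
* no progeny call carries an allele outside {a, b} (and all calls are ACGT),
* it is observed in enough progeny (missing fraction ≤ 30%), and
* its genotype counts do not deviate from 1:2:1 at P < 0.001 (Pearson χ²,
  2 df).

Markers with indistinguishable segregation (zero observed recombinants) are
then collapsed into bins, keeping one representative per map locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .util import ParseError, atomic_write

MISSING = "--"

#: CP-model parental configurations, plus a bucket for monomorphic loci.
PATTERNS = (
    "efxeg",
    "nnxnp",
    "abxcc",
    "aaxbb",
    "abxcd",
    "lmxll",
    "hkxhk",
    "ccxab",
    "unclassifiable",
)

FILTER_REASONS = ("kept", "not_aa_bb", "too_many_genotypes", "distorted", "missing_excess")

_VALID_ALLELES = frozenset("ACGT")
#: IUPAC nucleotide letters accepted by the parser; calls containing a
#: non-ACGT code survive parsing but fail the abnormal-base filter.
_IUPAC = frozenset("ACGTURYSWKMBDVHN")


def normalize_call(token: str) -> str:
    """Normalize a genotype token ('A/G', 'GA', '--') to a sorted 2-char string."""
    token = token.strip().upper().replace("/", "")
    if token in ("", MISSING, "-"):
        return MISSING
    if len(token) == 1:  # haploid-style shorthand: treat as homozygous
        token = token * 2
    if len(token) != 2 or not set(token) <= _IUPAC:
        raise ValueError(f"bad genotype token {token!r}")
    return "".join(sorted(token))


@dataclass
class GenotypeMatrix:
    """Parental and F2 genotype calls for a set of SNP markers.

    ``markers`` has one row per marker with columns ``marker``, ``scaffold``,
    ``position`` (1-based bp on the scaffold), ``p1`` and ``p2`` (parental
    calls as sorted 2-character strings).  ``calls`` is an (n_markers ×
    n_individuals) array of sorted 2-character genotype strings, ``--`` for
    missing.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype="<U2")
        if len(self.markers) != self.calls.shape[0]:
            raise ValueError("markers and calls row counts differ")
        if not self.individuals:
            self.individuals = [f"ind_{i + 1}" for i in range(self.calls.shape[1])]
        if len(self.individuals) != self.calls.shape[1]:
            raise ValueError("individual names and calls column counts differ")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def subset(self, row_index) -> "GenotypeMatrix":
        idx = np.asarray(row_index)
        return GenotypeMatrix(
            self.markers.iloc[idx].reset_index(drop=True),
            self.calls[idx],
            list(self.individuals),
        )

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with atomic_write(path) as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            cols = ["marker", "scaffold", "position", "P1", "P2", *self.individuals]
            fh.write("\t".join(cols) + "\n")
            for i, row in enumerate(self.markers.itertuples(index=False)):
                fh.write(
                    "\t".join(
                        [
                            str(row.marker),
                            str(row.scaffold),
                            str(row.position),
                            row.p1,
                            row.p2,
                            *self.calls[i],
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        rows, calls = [], []
        individuals: list[str] = []
        with open(path) as fh:
            lineno = 0
            header: list[str] | None = None
            for line in fh:
                lineno += 1
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if header is None:
                    header = parts
                    if len(header) < 6 or header[:5] != ["marker", "scaffold", "position", "P1", "P2"]:
                        raise ParseError(
                            f"{path}:{lineno}: expected header 'marker scaffold position P1 P2 ind...'"
                        )
                    individuals = header[5:]
                    continue
                if len(parts) != len(header):
                    raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}")
                try:
                    p1, p2 = normalize_call(parts[3]), normalize_call(parts[4])
                    row_calls = [normalize_call(t) for t in parts[5:]]
                    pos = int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
                rows.append((parts[0], parts[1], pos, p1, p2))
                calls.append(row_calls)
        if header is None:
            raise ParseError(f"{path}:1: empty genotype table")
        markers = pd.DataFrame(rows, columns=["marker", "scaffold", "position", "p1", "p2"])
        return cls(markers, np.asarray(calls, dtype="<U2"), individuals)


# ---------------------------------------------------------------------------
# CP-model pattern classification
# ---------------------------------------------------------------------------

def classify_pattern(parent1_call: str, parent2_call: str) -> str:
    """Classify the parental allele configuration into CP nomenclature.

    Raises ValueError on a missing parental call.
    """
    p1 = normalize_call(parent1_call)
    p2 = normalize_call(parent2_call)
    if p1 == MISSING or p2 == MISSING:
        raise ValueError("parental call is missing; pattern undefined")
    s1, s2 = set(p1), set(p2)
    het1, het2 = len(s1) == 2, len(s2) == 2
    shared = len(s1 & s2)
    if not het1 and not het2:
        return "aaxbb" if s1 != s2 else "unclassifiable"
    if het1 and not het2:
        return "lmxll" if shared else "abxcc"
    if not het1 and het2:
        return "nnxnp" if shared else "ccxab"
    # both heterozygous
    if s1 == s2:
        return "hkxhk"
    return "efxeg" if shared == 1 else "abxcd"


def classify_patterns(matrix: GenotypeMatrix) -> pd.Series:
    """Pattern per marker, indexed like ``matrix.markers``."""
    pats = [classify_pattern(r.p1, r.p2) for r in matrix.markers.itertuples(index=False)]
    return pd.Series(pats, name="pattern")


def pattern_counts(matrix: GenotypeMatrix) -> pd.Series:
    """Number of markers in each of the eight CP classes (plus unclassifiable)."""
    pats = classify_patterns(matrix)
    return pats.value_counts().reindex(PATTERNS, fill_value=0)


# ---------------------------------------------------------------------------
# Segregation-distortion test and filter chain
# ---------------------------------------------------------------------------

def chi_square_1_2_1(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson χ² of observed genotype counts against 1:2:1, 2 df.

    Returns (statistic, upper-tail p-value).
    """
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if obs.min() < 0 or obs.sum() < 1:
        raise ValueError("counts must be non-negative with a positive total")
    total = obs.sum()
    expected = total * np.array([0.25, 0.5, 0.25])
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), float(p)


def encode_dosage(matrix: GenotypeMatrix) -> np.ndarray:
    """Code calls at aa×bb markers as 0 (aa), 1 (ab), 2 (bb); -1 otherwise.

    The coding uses parent 1's allele as *a* and parent 2's as *b*; rows whose
    parents are not both homozygous code every call -1.
    """
    out = np.full(matrix.calls.shape, -1, dtype=np.int8)
    for i, row in enumerate(matrix.markers.itertuples(index=False)):
        s1, s2 = set(row.p1), set(row.p2)
        if len(s1) != 1 or len(s2) != 1 or s1 == s2:
            continue
        a, b = row.p1[0], row.p2[0]
        col = matrix.calls[i]
        out[i][col == a + a] = 0
        out[i][col == "".join(sorted(a + b))] = 1
        out[i][col == b + b] = 2
    return out


def filter_markers(
    matrix: GenotypeMatrix,
    p_threshold: float = 0.001,
    max_missing: float = 0.30,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the aa×bb retention rules; return (retained matrix, verdicts).

    The verdict table has one row per input marker with columns ``marker``,
    ``kept``, ``reason``, ``chi2_statistic``, ``p_value`` and
    ``missing_fraction``; the χ² columns are NaN when the distortion test did
    not run (the test is only defined for clean aa×bb markers).  Removal is
    strict: a marker is dropped for missingness only when its missing
    fraction exceeds ``max_missing``, and for distortion only when
    p < ``p_threshold``.
    """
    if matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    patterns = classify_patterns(matrix)
    dosage = encode_dosage(matrix)
    miss = matrix.missing_fraction()
    n = matrix.n_individuals

    reasons = np.full(matrix.n_markers, "kept", dtype=object)
    chi2_stat = np.full(matrix.n_markers, np.nan)
    p_val = np.full(matrix.n_markers, np.nan)

    for i in range(matrix.n_markers):
        if patterns.iloc[i] != "aaxbb":
            reasons[i] = "not_aa_bb"
            continue
        calls = matrix.calls[i]
        observed = calls != MISSING
        # alien allele / non-ACGT progeny call: dosage -1 on an observed call
        if np.any((dosage[i] < 0) & observed):
            reasons[i] = "too_many_genotypes"
            continue
        if miss[i] > max_missing:
            reasons[i] = "missing_excess"
            continue
        counts = np.bincount(dosage[i][observed], minlength=3)
        if counts.sum() == 0:
            reasons[i] = "missing_excess"
            continue
        chi2_stat[i], p_val[i] = chi_square_1_2_1(*counts)
        if p_val[i] < p_threshold:
            reasons[i] = "distorted"

    verdicts = pd.DataFrame(
        {
            "marker": matrix.markers["marker"],
            "kept": reasons == "kept",
            "reason": reasons,
            "chi2_statistic": chi2_stat,
            "p_value": p_val,
            "missing_fraction": miss,
        }
    )
    retained = matrix.subset(np.flatnonzero(verdicts["kept"].to_numpy()))
    return retained, verdicts


# ---------------------------------------------------------------------------
# Bin collapsing
# ---------------------------------------------------------------------------

def collapse_bins(
    matrix: GenotypeMatrix,
    min_common_fraction: float = 0.5,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Collapse markers with indistinguishable segregation into bins.

    Two markers co-bin when their genotype calls agree at every commonly
    observed individual (zero observed recombinants) *and* at least
    ``min_common_fraction`` of individuals are commonly observed — the latter
    guards against spurious bins between sparsely observed markers.  The
    representative of a bin is its member with the lexicographically smallest
    (scaffold, position).  Membership is assigned greedily against existing
    representatives in that sort order, which makes the operation idempotent.

    Returns (matrix of representatives, membership table with columns
    ``bin``, ``representative``, ``marker``).
    """
    n = matrix.n_individuals
    dosage = encode_dosage(matrix)
    order = matrix.markers.sort_values(
        ["scaffold", "position", "marker"], kind="mergesort"
    ).index.to_numpy()

    rep_rows: list[int] = []
    membership: list[tuple[int, int]] = []  # (rep row, member row)
    min_common = min_common_fraction * n
    for row in order:
        d = dosage[row]
        obs = d >= 0
        placed = False
        for b, rep in enumerate(rep_rows):
            dr = dosage[rep]
            common = obs & (dr >= 0)
            if common.sum() >= min_common and np.array_equal(d[common], dr[common]):
                membership.append((b, row))
                placed = True
                break
        if not placed:
            rep_rows.append(row)
            membership.append((len(rep_rows) - 1, row))

    ids = matrix.markers["marker"]
    bins = pd.DataFrame(
        {
            "bin": [f"bin_{b + 1:05d}" for b, _ in membership],
            "representative": [ids.iloc[rep_rows[b]] for b, _ in membership],
            "marker": [ids.iloc[r] for _, r in membership],
        }
    ).sort_values(["bin", "marker"], kind="mergesort").reset_index(drop=True)
    representatives = matrix.subset(rep_rows)
    return representatives, bins
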