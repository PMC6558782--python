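"""Truth-known simulation of a fragmented genome and an F2 mapping population.

The generator emulates the study design the pipeline targets: a diploid
plant genome of 14 chromosomes whose assembly exists only as ordered,
oriented scaffolds; an F2 population of 111 individuals genotyped at SNP
markers spread along the scaffolds; and planted transcripts and SSR primer
sites to exercise feature placement and coordinate liftover.  Every stage
records its ground truth so downstream results can be scored exactly.

Meiosis is modeled per gamete and chromosome with a Poisson crossover count
(Haldane's no-interference model) and uniform crossover positions on the cM
scale; the mapping stage nevertheless uses the Kosambi function downstream,
mirroring common practice on real data — the small systematic discrepancy
is intentional and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .segpattern import GenotypeMatrix, MISSING
from .util import ConfigurationError, atomic_write, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the simulated cross and genome.

    Defaults mirror the target design (14 chromosomes, 111 F2 individuals)
    at desk scale: 500 kb chromosomes cut into 12 scaffolds each (168
    scaffolds genome-wide), 4 markers per scaffold, and 150 cM of genetic
    length per chromosome.
    """

    n_chromosomes: int = 14
    chromosome_length_bp: int = 500_000
    n_scaffolds_per_chromosome: int = 12
    n_individuals: int = 111
    markers_per_scaffold: int = 4
    genetic_length_cM: float = 150.0
    missing_rate: float = 0.05
    error_rate: float = 0.01
    distorted_fraction: float = 0.10
    non_aabb_fraction: float = 0.10
    n_transcripts: int = 30
    n_ssrs: int = 20
    gap_truth_bp: int = 100
    rng_seed: int = 0

    def validate(self) -> None:
        counts = (
            "n_chromosomes",
            "chromosome_length_bp",
            "n_scaffolds_per_chromosome",
            "n_individuals",
            "markers_per_scaffold",
            "n_transcripts",
            "n_ssrs",
            "gap_truth_bp",
        )
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("missing_rate", "error_rate", "distorted_fraction", "non_aabb_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if self.genetic_length_cM <= 0:
            raise ConfigurationError(f"genetic_length_cM must be positive, got {self.genetic_length_cM}")
        if self.chromosome_length_bp < self.n_scaffolds_per_chromosome * 1000:
            raise ConfigurationError(
                "chromosome_length_bp too small: need >= 1000 bp per scaffold "
                f"({self.chromosome_length_bp} < {self.n_scaffolds_per_chromosome * 1000})"
            )

    def to_txt(self, path) -> None:
        with atomic_write(path) as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_txt(cls, path) -> "SimulationConfig":
        kwargs = {}
        fields_ = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                k = k.strip()
                if k not in fields_:
                    raise ConfigurationError(f"unknown configuration key {k!r}")
                typ = float if fields_[k] == "float" else int
                kwargs[k] = typ(v.strip())
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Ground truth accumulated across the simulation stages.

    scaffolds: scaffold, chromosome, rank, orientation, chrom_start, length
    markers:   marker, scaffold, position, chromosome, chrom_pos, cM,
               allele_a, allele_b, category
    features:  feature, kind, scaffold, scaffold start/end/strand,
               chromosome, chrom start/end/strand
    """

    scaffolds: pd.DataFrame = field(default_factory=pd.DataFrame)
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir) -> None:
        import os

        for name in ("scaffolds", "markers", "features"):
            df = getattr(self, name)
            with atomic_write(os.path.join(outdir, f"truth_{name}.tsv")) as fh:
                df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome and scaffolds
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Generate the chromosome sequences; returns (chromosomes, empty truth)."""
    config.validate()
    rng = rng or np.random.default_rng(config.rng_seed)
    chroms = {
        f"chrom_{c + 1:02d}": _random_sequence(rng, config.chromosome_length_bp)
        for c in range(config.n_chromosomes)
    }
    return chroms, SimulationTruth()


def fragment_into_scaffolds(
    chromosomes: dict[str, str],
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    min_len: int = 1000,
    max_retries: int = 100,
):
    """Cut each chromosome into scaffolds, flip half, shuffle identifiers.

    Pieces shorter than ``min_len`` trigger breakpoint resampling (bounded
    retries).  Truth records (chromosome, rank, orientation, chrom_start,
    length) per scaffold.
    """
    n_total = len(chromosomes) * config.n_scaffolds_per_chromosome
    names = [f"scf_{i + 1:04d}" for i in range(n_total)]
    rng.shuffle(names)
    name_iter = iter(names)

    scaffolds: dict[str, str] = {}
    rows = []
    for chrom, seq in chromosomes.items():
        L = len(seq)
        k = config.n_scaffolds_per_chromosome
        if L < k * min_len:
            raise RuntimeError(f"{chrom}: cannot cut {L} bp into {k} pieces of >= {min_len} bp")
        if k == 1:
            bounds = np.array([0, L])
        else:
            for attempt in range(max_retries):
                # reduced-interval draw: uniform cuts with the minimum piece
                # length added back cannot produce a short piece
                slack = np.sort(rng.integers(0, L - k * min_len + 1, size=k - 1))
                cuts = slack + min_len * np.arange(1, k)
                bounds = np.concatenate([[0], cuts, [L]])
                if np.diff(bounds).min() >= min_len:
                    break
            else:  # pragma: no cover - unreachable with the reduced draw
                raise RuntimeError(
                    f"could not cut {chrom} into {k} pieces of >= {min_len} bp "
                    f"after {max_retries} attempts"
                )
        for rank in range(k):
            a, b = int(bounds[rank]), int(bounds[rank + 1])
            piece = seq[a:b]
            orientation = "+" if rng.random() < 0.5 else "-"
            name = next(name_iter)
            scaffolds[name] = piece if orientation == "+" else revcomp(piece)
            rows.append((name, chrom, rank + 1, orientation, a + 1, b - a))
    truth.scaffolds = pd.DataFrame(
        rows, columns=["scaffold", "chromosome", "rank", "orientation", "chrom_start", "length"]
    )
    # emit scaffolds in shuffled-id order so input order carries no signal
    scaffolds = {k: scaffolds[k] for k in sorted(scaffolds)}
    return scaffolds, truth


def reassemble_from_truth(
    scaffolds: dict[str, str], truth: SimulationTruth, gap_bp: int = 0
) -> dict[str, str]:
    """Rebuild chromosomes from scaffolds using the recorded truth.

    With ``gap_bp=0`` the result is byte-identical to the simulated
    chromosomes (inverse-operation identity); a positive gap reproduces what
    a perfect anchoring with that spacer would build.
    """
    out = {}
    for chrom, grp in truth.scaffolds.groupby("chromosome"):
        parts = []
        for row in grp.sort_values("rank").itertuples(index=False):
            s = scaffolds[row.scaffold]
            parts.append(s if row.orientation == "+" else revcomp(s))
        out[chrom] = ("N" * gap_bp).join(parts)
    return out


# ---------------------------------------------------------------------------
# Markers and the F2 cross
# ---------------------------------------------------------------------------

def _scaffold_to_chrom(pos: int, orientation: str, chrom_start: int, length: int) -> int:
    """1-based scaffold coordinate -> 1-based chromosome coordinate."""
    if orientation == "+":
        return chrom_start + pos - 1
    return chrom_start + (length - pos)


def plant_markers(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    edge_margin: int = 51,
) -> SimulationTruth:
    """Place SNP markers on every scaffold and assign segregation categories.

    Marker cM positions follow a uniform recombination landscape:
    cM = genetic_length × (chromosome position / chromosome length).  A
    fraction of markers receives a non-aa×bb parental pattern and a further
    fraction of the aa×bb markers is labeled ``distorted`` (their F2 calls
    will be resampled from a 9:5:2 ratio).
    """
    rows = []
    for scf in truth.scaffolds.itertuples(index=False):
        lo, hi = edge_margin, scf.length - edge_margin + 1
        if hi <= lo:
            raise ConfigurationError(
                f"scaffold {scf.scaffold} too short ({scf.length} bp) for markers"
            )
        m = config.markers_per_scaffold
        positions = np.sort(rng.choice(np.arange(lo, hi), size=m, replace=False))
        for pos in positions:
            cpos = _scaffold_to_chrom(int(pos), scf.orientation, scf.chrom_start, scf.length)
            cm = config.genetic_length_cM * cpos / config.chromosome_length_bp
            a, b = rng.choice(4, size=2, replace=False)
            rows.append(
                (scf.scaffold, int(pos), scf.chromosome, cpos, cm, "ACGT"[a], "ACGT"[b])
            )
    mk = pd.DataFrame(
        rows,
        columns=["scaffold", "position", "chromosome", "chrom_pos", "cM", "allele_a", "allele_b"],
    )
    n = len(mk)
    ids = [f"snp_{i + 1:06d}" for i in range(n)]
    rng.shuffle(ids)
    mk.insert(0, "marker", ids)

    category = np.full(n, "aabb", dtype=object)
    n_other = int(round(config.non_aabb_fraction * n))
    other_idx = rng.choice(n, size=n_other, replace=False)
    category[other_idx] = rng.choice(["lmxll", "nnxnp", "hkxhk"], size=n_other)
    aabb_idx = np.flatnonzero(category == "aabb")
    n_dist = int(round(config.distorted_fraction * n))
    n_dist = min(n_dist, aabb_idx.size)
    category[rng.choice(aabb_idx, size=n_dist, replace=False)] = "distorted"
    mk["category"] = category

    truth.markers = mk.sort_values("marker", kind="mergesort").reset_index(drop=True)
    return truth


#: F2 genotype frequencies used for markers labeled ``distorted``; chosen so
#: the 1:2:1 χ² rejects at P < 0.001 essentially always at n = 111.
DISTORTED_RATIO = (9, 5, 2)


def simulate_f2(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Simulate the F2 genotype matrix from the planted marker truth.

    Each individual is the union of two independent F1 gametes; per gamete
    and chromosome, the crossover count is Poisson(map length in Morgans)
    with uniform crossover positions and no interference.  Perturbations
    (distorted-ratio resampling, genotyping errors, missing calls) are then
    applied in that order.
    """
    if truth.markers.empty:
        raise ValueError("no marker loci planted; run plant_markers first")
    mk = truth.markers
    n_mark, n_ind = len(mk), config.n_individuals
    dosage = np.zeros((n_mark, n_ind), dtype=np.int8)

    L_cm = config.genetic_length_cM
    for chrom, grp in mk.groupby("chromosome"):
        rows = grp.index.to_numpy()
        cm = grp["cM"].to_numpy()
        alleles = np.zeros((2, len(rows), n_ind), dtype=np.int8)
        for g in range(2):
            for ind in range(n_ind):
                n_x = rng.poisson(L_cm / 100.0)
                xpos = np.sort(rng.uniform(0.0, L_cm, n_x))
                start = rng.integers(0, 2)
                alleles[g, :, ind] = (start + np.searchsorted(xpos, cm)) % 2
        dosage[rows] = alleles.sum(axis=0)

    is_aabb = (mk["category"] == "aabb") | (mk["category"] == "distorted")

    # distorted markers: resample i.i.d. from the distorted ratio
    probs = np.array(DISTORTED_RATIO, dtype=float)
    probs /= probs.sum()
    for i in np.flatnonzero((mk["category"] == "distorted").to_numpy()):
        dosage[i] = rng.choice(3, size=n_ind, p=probs)

    # non-aa×bb parental patterns: i.i.d. draws from the pattern's F1-style mix
    pattern_probs = {
        "lmxll": [0.5, 0.5, 0.0],
        "nnxnp": [0.5, 0.5, 0.0],
        "hkxhk": [0.25, 0.5, 0.25],
    }
    for i in np.flatnonzero((~is_aabb).to_numpy()):
        dosage[i] = rng.choice(3, size=n_ind, p=pattern_probs[mk["category"].iloc[i]])

    # genotyping errors: replace with a uniformly random *other* genotype
    if config.error_rate > 0:
        err = rng.random(dosage.shape) < config.error_rate
        shift = rng.integers(1, 3, size=dosage.shape)
        dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)

    miss = (
        rng.random(dosage.shape) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros(dosage.shape, dtype=bool)
    )

    # genotype strings per marker
    calls = np.empty((n_mark, n_ind), dtype="<U2")
    p1 = np.empty(n_mark, dtype="<U2")
    p2 = np.empty(n_mark, dtype="<U2")
    for i, row in enumerate(mk.itertuples(index=False)):
        a, b = row.allele_a, row.allele_b
        g = [a + a, "".join(sorted(a + b)), b + b]
        calls[i] = np.array(g, dtype="<U2")[dosage[i]]
        if row.category in ("aabb", "distorted"):
            p1[i], p2[i] = g[0], g[2]
        elif row.category == "lmxll":
            p1[i], p2[i] = g[1], g[0]
        elif row.category == "nnxnp":
            p1[i], p2[i] = g[0], g[1]
        else:  # hkxhk
            p1[i], p2[i] = g[1], g[1]
    calls[miss] = MISSING

    markers = pd.DataFrame(
        {
            "marker": mk["marker"],
            "scaffold": mk["scaffold"],
            "position": mk["position"],
            "p1": p1,
            "p2": p2,
        }
    )
    return GenotypeMatrix(markers, calls)


# ---------------------------------------------------------------------------
# Planted features (transcripts and SSR primer pairs)
# ---------------------------------------------------------------------------

def _unique_on_genome(genome: str, site: str) -> bool:
    """True iff ``site`` occurs exactly once counting both strands."""
    return genome.count(site) + genome.count(revcomp(site)) == 1


def plant_features(
    scaffolds: dict[str, str],
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
):
    """Plant transcripts and SSR primer sites; record their coordinates.

    Transcripts are contiguous 0.3–8 kb substrings copied from either strand
    of a scaffold (so they never span a scaffold boundary).  An SSR locus is
    a 20 bp forward-primer site with the reverse complement of a 20 bp
    reverse primer ending 139–389 bp downstream; both sites must be unique
    genome-wide, with bounded retries.

    Returns (transcripts, primer table, truth).
    """
    if truth.scaffolds.empty:
        raise ValueError("genome not fragmented; run fragment_into_scaffolds first")
    genome = "#".join(scaffolds.values())
    scf = truth.scaffolds.set_index("scaffold")
    scf_ids = sorted(scaffolds)
    lengths = np.array([len(scaffolds[s]) for s in scf_ids])

    def lift_truth(s: str, start: int, end: int, strand: str):
        row = scf.loc[s]
        if row.orientation == "+":
            cs, ce, cstr = row.chrom_start + start - 1, row.chrom_start + end - 1, strand
        else:
            cs = row.chrom_start + (row.length - end)
            ce = row.chrom_start + (row.length - start)
            cstr = {"+": "-", "-": "+", ".": "."}[strand]
        return row.chromosome, int(cs), int(ce), cstr

    feat_rows = []
    transcripts: dict[str, str] = {}
    for t in range(config.n_transcripts):
        tlen = int(rng.integers(300, 8001))
        eligible = np.flatnonzero(lengths >= tlen)
        if eligible.size == 0:
            tlen = int(lengths.max())
            eligible = np.flatnonzero(lengths >= tlen)
        s = scf_ids[int(rng.choice(eligible))]
        start = int(rng.integers(1, len(scaffolds[s]) - tlen + 2))
        end = start + tlen - 1
        strand = "+" if rng.random() < 0.5 else "-"
        seq = scaffolds[s][start - 1 : end]
        name = f"tx_{t + 1:05d}"
        transcripts[name] = seq if strand == "+" else revcomp(seq)
        feat_rows.append((name, "transcript", s, start, end, strand, *lift_truth(s, start, end, strand)))

    primer_rows = []
    for k in range(config.n_ssrs):
        for attempt in range(max_retries):
            amp = int(rng.integers(140, 390))
            eligible = np.flatnonzero(lengths >= amp)
            s = scf_ids[int(rng.choice(eligible))]
            seq = scaffolds[s]
            start = int(rng.integers(1, len(seq) - amp + 2))
            end = start + amp - 1
            fwd = seq[start - 1 : start + 19]
            rev = revcomp(seq[end - 20 : end])
            if (
                set(fwd) <= set("ACGT")
                and set(rev) <= set("ACGT")
                and _unique_on_genome(genome, fwd)
                and _unique_on_genome(genome, rev)
            ):
                break
        else:
            raise RuntimeError(f"could not plant a unique SSR site after {max_retries} attempts")
        name = f"ssr_{k + 1:05d}"
        primer_rows.append((name, fwd, rev))
        feat_rows.append((name, "ssr", s, start, end, "+", *lift_truth(s, start, end, "+")))

    truth.features = pd.DataFrame(
        feat_rows,
        columns=[
            "feature",
            "kind",
            "scaffold",
            "scaffold_start",
            "scaffold_end",
            "scaffold_strand",
            "chromosome",
            "chrom_start",
            "chrom_end",
            "chrom_strand",
        ],
    )
    primers = pd.DataFrame(primer_rows, columns=["ssr", "forward", "reverse"])
    return transcripts, primers, truth


# ---------------------------------------------------------------------------
# One-call orchestration and truth-based scoring
# ---------------------------------------------------------------------------

@dataclass
class SimulationDataset:
    config: SimulationConfig
    chromosomes: dict[str, str]
    scaffolds: dict[str, str]
    genotypes: GenotypeMatrix
    transcripts: dict[str, str]
    ssr_primers: pd.DataFrame
    truth: SimulationTruth


def simulate_dataset(config: SimulationConfig, include_features: bool = True) -> SimulationDataset:
    """Run every simulation stage from one seed; deterministic per seed."""
    rng = np.random.default_rng(config.rng_seed)
    chroms, truth = simulate_genome(config, rng)
    scaffolds, truth = fragment_into_scaffolds(chroms, truth, config, rng)
    truth = plant_markers(truth, config, rng)
    genotypes = simulate_f2(truth, config, rng)
    if include_features:
        transcripts, primers, truth = plant_features(scaffolds, truth, config, rng)
    else:
        transcripts, primers = {}, pd.DataFrame(columns=["ssr", "forward", "reverse"])
    return SimulationDataset(config, chroms, scaffolds, genotypes, transcripts, primers, truth)


def marker_flanks(ds: SimulationDataset, flank_bp: int = 101) -> dict[str, str]:
    """Flanking sequence (centered on the SNP) per marker, from its scaffold."""
    half = flank_bp // 2
    out = {}
    for row in ds.truth.markers.itertuples(index=False):
        seq = ds.scaffolds[row.scaffold]
        lo = max(0, row.position - 1 - half)
        out[row.marker] = seq[lo : row.position + half]
    return out


def score_scaffold_recovery(placements: pd.DataFrame, truth: SimulationTruth) -> dict:
    """Score anchoring against the simulation truth, up to whole-chromosome
    reversal.

    ``placements`` needs columns scaffold, chromosome (group id), rank,
    orientation.  Each recovered group is matched to the true chromosome
    holding the majority of its scaffolds; within a group the polarity
    (forward or reversed) maximizing joint order+orientation agreement is
    chosen.  Fractions are over all true scaffolds, so unplaced scaffolds
    count as failures.

    The strict orientation fraction counts a defaulted (orientation-unknown)
    scaffold as incorrect whenever the default misses the truth; the
    ``decided`` metrics restrict to scaffolds where the concordance test
    actually committed to an orientation, which separates algorithmic error
    from abstention on information-free scaffolds.
    """
    tr = truth.scaffolds.set_index("scaffold")
    n_total = len(tr)
    assigned_ok = ordered_ok = oriented_ok = both_ok = 0
    decided = decided_ok = 0

    for group, grp in placements.groupby("chromosome"):
        grp = grp.sort_values("rank")
        true_chrom = grp["scaffold"].map(tr["chromosome"]).mode().iloc[0]
        correct = grp[grp["scaffold"].map(tr["chromosome"]) == true_chrom]
        assigned_ok += len(correct)
        seq = correct["scaffold"].tolist()  # recovered relative order
        truth_seq = sorted(seq, key=lambda s: tr.loc[s, "rank"])
        best = None
        for reversed_ in (False, True):
            rec = seq[::-1] if reversed_ else seq
            order_flags = {s: rec.index(s) == truth_seq.index(s) for s in seq}
            orient_flags = {}
            dec_flags = {}
            for row in correct.itertuples(index=False):
                o = row.orientation
                if reversed_:
                    o = "-" if o == "+" else "+"
                orient_flags[row.scaffold] = o == tr.loc[row.scaffold, "orientation"]
                if row.orientation_known:
                    dec_flags[row.scaffold] = orient_flags[row.scaffold]
            n_both = sum(order_flags[s] and orient_flags[s] for s in seq)
            cand = (n_both, sum(order_flags.values()), sum(orient_flags.values()), dec_flags)
            if best is None or cand[:3] > best[:3]:
                best = cand
        both_ok += best[0]
        ordered_ok += best[1]
        oriented_ok += best[2]
        decided += len(best[3])
        decided_ok += sum(best[3].values())

    return {
        "n_scaffolds": n_total,
        "frac_assigned": assigned_ok / n_total,
        "frac_ordered": ordered_ok / n_total,
        "frac_oriented": oriented_ok / n_total,
        "frac_ordered_and_oriented": both_ok / n_total,
        "n_orientation_decided": decided,
        "frac_decided_orientation_correct": decided_ok / decided if decided else 1.0,
    }


def write_dataset(ds: SimulationDataset, outdir) -> None:
    """Write every simulated artifact in its plain-text exchange format."""
    import os

    from .util import write_fasta

    os.makedirs(outdir, exist_ok=True)
    seed = ds.config.rng_seed
    write_fasta(ds.chromosomes, os.path.join(outdir, "chromosomes.fasta"))
    write_fasta(ds.scaffolds, os.path.join(outdir, "scaffolds.fasta"))
    if ds.transcripts:
        write_fasta(ds.transcripts, os.path.join(outdir, "transcripts.fasta"))
    ds.genotypes.to_tsv(os.path.join(outdir, "genotypes.tsv"), header_comment=f"mapanchor seed={seed}")
    with atomic_write(os.path.join(outdir, "ssr_primers.tsv")) as fh:
        fh.write(f"# mapanchor seed={seed}\n")
        ds.ssr_primers.to_csv(fh, sep="\t", index=False)
    ds.config.to_txt(os.path.join(outdir, "config.txt"))
    ds.truth.write(outdir)
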