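"""Transcript mapping, in-silico PCR, and coordinate liftover."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapanchor import (
    epcr_locate,
    integrate_features,
    inverse_lift_interval,
    lift_interval,
    map_transcript,
    map_transcripts,
)
from mapanchor.liftover import locate_ssrs, snp_intervals, lift_features
from mapanchor.util import revcomp


# ---------------------------------------------------------------------------
# Transcript mapping
# ---------------------------------------------------------------------------

def test_planted_transcripts_map_back_to_truth(clean_ds):
    hits = map_transcripts(clean_ds.transcripts, clean_ds.scaffolds).set_index("feature")
    truth = clean_ds.truth.features.set_index("feature")
    for feature in hits.index:
        t = truth.loc[feature]
        h = hits.loc[feature]
        assert h["status"] == "unique"
        assert h["scaffold"] == t["scaffold"]
        assert (h["start"], h["end"]) == (t["scaffold_start"], t["scaffold_end"])
        assert h["strand"] == t["scaffold_strand"]


def test_unrelated_sequence_is_unmapped(clean_ds):
    rng = np.random.default_rng(99)
    decoy = "".join(rng.choice(list("ACGT"), 1000))
    row = map_transcript("decoy", decoy, clean_ds.scaffolds)
    assert row[6] == "unmapped"


def test_multi_hit_transcript_is_flagged_ambiguous():
    block = "ACGTTGCAAGGCTTAGGCTA" * 10
    scaffolds = {"s1": "T" * 30 + block + "A" * 30 + block + "G" * 30}
    row = map_transcript("t", block, scaffolds)
    assert row[6] == "ambiguous"
    assert row[3] == 31  # first hit by coordinate


def test_short_transcript_not_searched():
    row = map_transcript("t", "ACGT" * 10, {"s1": "ACGT" * 100})
    assert row[6] == "too_short"


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _scaffold_with_site(amp_len, rng):
    seq = list(rng.choice(list("ACGT"), 3000))
    fwd = "".join(rng.choice(list("ACGT"), 20))
    rev = "".join(rng.choice(list("ACGT"), 20))
    start = 1000
    seq[start : start + 20] = fwd
    seq[start + amp_len - 20 : start + amp_len] = revcomp(rev)
    return "".join(seq), fwd, rev, start + 1


def test_planted_amplicon_is_recovered_exactly():
    rng = np.random.default_rng(4)
    seq, fwd, rev, start = _scaffold_with_site(150, rng)
    loci = epcr_locate(fwd, rev, {"s1": seq})
    assert len(loci) == 1
    row = loci.iloc[0]
    assert (row["start"], row["end"] - row["start"] + 1, row["strand"]) == (start, 150, "+")


def test_amplicon_bound_is_strict():
    rng = np.random.default_rng(5)
    seq, fwd, rev, _ = _scaffold_with_site(450, rng)
    assert epcr_locate(fwd, rev, {"s1": seq}).empty
    seq, fwd, rev, _ = _scaffold_with_site(400, rng)
    assert epcr_locate(fwd, rev, {"s1": seq}).empty  # outer length 400 is not < 400
    seq, fwd, rev, _ = _scaffold_with_site(399, rng)
    assert len(epcr_locate(fwd, rev, {"s1": seq})) == 1


def test_single_mismatch_defeats_the_primer():
    rng = np.random.default_rng(6)
    seq, fwd, rev, start = _scaffold_with_site(150, rng)
    mism = list(fwd)
    mism[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mism[10]]
    assert epcr_locate("".join(mism), rev, {"s1": seq}).empty


def test_minus_strand_site_is_found():
    rng = np.random.default_rng(7)
    seq, fwd, rev, start = _scaffold_with_site(150, rng)
    flipped = {"s1": revcomp(seq)}
    loci = epcr_locate(fwd, rev, flipped)
    assert len(loci) == 1
    assert loci.iloc[0]["strand"] == "-"
    assert loci.iloc[0]["end"] - loci.iloc[0]["start"] + 1 == 150


def test_epcr_matches_bruteforce_scan():
    """Every reported locus matches an exhaustive O(n²) primer-site scan."""
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), 10_000))
    fwd = seq[2000:2015]  # 15-mer primers occur a few times by chance
    rev = revcomp(seq[2200:2215])
    loci = epcr_locate(fwd, rev, {"s1": seq}, max_amplicon=400)

    expected = set()
    for s in range(len(seq)):
        if seq.startswith(fwd, s):
            for e in range(s + 1, min(s + 400, len(seq) + 1)):
                if seq.endswith(revcomp(rev), 0, e) and (e - s) < 400:
                    expected.add((s + 1, e, "+"))
        if seq.startswith(rev, s):
            for e in range(s + 1, min(s + 400, len(seq) + 1)):
                if seq.endswith(revcomp(fwd), 0, e) and (e - s) < 400:
                    expected.add((s + 1, e, "-"))
    got = {(r.start, r.end, r.strand) for r in loci.itertuples(index=False)}
    assert got == expected


def test_invalid_primer_rejected():
    with pytest.raises(ValueError):
        epcr_locate("ACGT", "ACGTACGTACGTACGTACGT", {"s": "ACGT" * 100})
    with pytest.raises(ValueError):
        epcr_locate("ACGTNACGTACGTACGTACG", "ACGTACGTACGTACGTACGT", {"s": "ACGT" * 100})


def test_planted_ssrs_locate_uniquely(clean_ds):
    hits = locate_ssrs(clean_ds.ssr_primers, clean_ds.scaffolds).set_index("feature")
    truth = clean_ds.truth.features.set_index("feature")
    for ssr in hits.index:
        assert hits.loc[ssr, "status"] == "unique"
        assert hits.loc[ssr, "scaffold"] == truth.loc[ssr, "scaffold"]
        assert hits.loc[ssr, "start"] == truth.loc[ssr, "scaffold_start"]
        assert hits.loc[ssr, "end"] == truth.loc[ssr, "scaffold_end"]


# ---------------------------------------------------------------------------
# Coordinate liftover
# ---------------------------------------------------------------------------

def test_lift_interval_hand_walked_reverse():
    assert lift_interval(1, 3, "+", "-", 1, 10) == (8, 10, "-")
    assert lift_interval(1, 3, "+", "+", 1, 10) == (1, 3, "+")


@given(
    L=st.integers(5, 10_000),
    O=st.integers(1, 10_000),
    data=st.data(),
    orientation=st.sampled_from("+-"),
    strand=st.sampled_from(["+", "-", "."]),
)
@settings(max_examples=200, derandomize=True)
def test_lift_round_trip_and_length(L, O, data, orientation, strand):
    s = data.draw(st.integers(1, L))
    e = data.draw(st.integers(s, L))
    cs, ce, cstr = lift_interval(s, e, strand, orientation, O, L)
    assert ce - cs == e - s  # length preserved
    assert O <= cs <= ce <= O + L - 1
    back = inverse_lift_interval(cs, ce, cstr, orientation, O, L)
    assert back == (s, e, strand)


def test_lift_is_injective_per_scaffold():
    seen = set()
    for s in range(1, 30):
        for e in range(s, 30):
            out = lift_interval(s, e, "+", "-", 100, 30)[:2]
            assert out not in seen
            seen.add(out)


def test_out_of_bounds_interval_rejected():
    with pytest.raises(ValueError):
        lift_interval(0, 3, "+", "+", 1, 10)
    with pytest.raises(ValueError):
        lift_interval(5, 11, "+", "+", 1, 10)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _toy_placements():
    return pd.DataFrame(
        {
            "scaffold": ["sA", "sB"],
            "chromosome": ["LG01", "LG01"],
            "rank": [1, 2],
            "orientation": ["+", "-"],
            "orientation_known": [True, True],
            "mean_cM": [1.0, 2.0],
            "n_markers": [2, 2],
            "length": [1000, 500],
            "offset": [1, 1101],
        }
    )


def test_features_on_unplaced_scaffolds_stay_unanchored():
    feats = pd.DataFrame(
        {
            "feature": ["t1", "t2"],
            "kind": ["transcript", "transcript"],
            "scaffold": ["sA", "sUnplaced"],
            "start": [10, 10],
            "end": [100, 100],
            "strand": ["+", "+"],
            "status": ["unique", "unique"],
        }
    )
    lifted = lift_features(feats, _toy_placements())
    by = lifted.set_index("feature")
    assert bool(by.loc["t1", "anchored"]) is True
    assert bool(by.loc["t2", "anchored"]) is False
    assert pd.isna(by.loc["t2", "chrom_start"])


def test_integrate_counts_categories():
    tx = pd.DataFrame(
        {
            "feature": ["t1", "t2"],
            "kind": "transcript",
            "scaffold": ["sA", None],
            "start": [10, None],
            "end": [100, None],
            "strand": ["+", None],
            "status": ["unique", "unmapped"],
        }
    )
    snp = pd.DataFrame(
        {
            "feature": ["m1"],
            "kind": "snp",
            "scaffold": ["sB"],
            "start": [50],
            "end": [50],
            "strand": ["."],
            "status": ["unique"],
        }
    )
    feats, counts = integrate_features(tx, snp, pd.DataFrame(), _toy_placements())
    assert counts["transcript"] == {"total": 2, "mapped": 1, "anchored": 1, "ambiguous": 0}
    assert counts["snp"]["anchored"] == 1
    # snp on the minus-oriented scaffold: position 50 -> offset + L - 50
    row = feats[feats["feature"] == "m1"].iloc[0]
    assert row["chrom_start"] == row["chrom_end"] == 1101 + 500 - 50
    assert counts["snp"]["anchored"] <= counts["snp"]["mapped"] <= counts["snp"]["total"]


def test_empty_inputs_give_empty_table():
    feats, counts = integrate_features(
        pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), _toy_placements()
    )
    assert feats.empty
    assert counts == {}


def test_snp_intervals_from_genotypes(small_ds):
    snp = snp_intervals(small_ds.genotypes)
    assert (snp["start"] == snp["end"]).all()
    assert len(snp) == small_ds.genotypes.n_markers
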