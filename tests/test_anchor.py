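"""Marker placement, scaffold assignment/ordering/orientation, AGP assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mapanchor import (
    assign_scaffolds,
    build_map,
    build_pseudomolecules,
    filter_markers,
    marker_flanks,
    orient_scaffold,
    order_scaffolds,
    place_markers,
)
from mapanchor.anchor import write_agp, read_agp
from mapanchor.linkmap import GeneticMap
from mapanchor.util import revcomp


# ---------------------------------------------------------------------------
# place_markers
# ---------------------------------------------------------------------------

def test_planted_flanks_place_uniquely_at_truth(clean_ds):
    flanks = marker_flanks(clean_ds)
    placements, rejected = place_markers(flanks, clean_ds.scaffolds)
    truth = clean_ds.truth.markers.set_index("marker")
    hit = placements.set_index("marker")
    # random-genome 101-mers are unique, so nearly everything places
    assert len(placements) >= 0.99 * len(truth)
    for marker in hit.index:
        assert hit.loc[marker, "scaffold"] == truth.loc[marker, "scaffold"]
        assert hit.loc[marker, "position"] == truth.loc[marker, "position"]
        assert hit.loc[marker, "strand"] == "+"


def test_multi_scaffold_flank_is_discarded():
    site = "ACGTACGTACGTACGTACGTA" * 2
    scaffolds = {"s1": "T" * 50 + site + "G" * 50, "s2": "A" * 30 + site + "C" * 70}
    placements, rejected = place_markers({"m": site}, scaffolds)
    assert placements.empty
    assert rejected.iloc[0]["reason"] == "multiple_scaffolds"


def test_reverse_complement_flank_places_with_minus_strand():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), 400))
    flank = seq[100:201]  # SNP base at 0-based 150
    placements, _ = place_markers({"m": revcomp(flank)}, {"s1": seq})
    row = placements.iloc[0]
    assert (row["scaffold"], row["position"], row["strand"]) == ("s1", 151, "-")


def test_short_flank_is_skipped():
    placements, rejected = place_markers({"m": "ACGTACGT"}, {"s1": "A" * 100})
    assert rejected.iloc[0]["reason"] == "flank_too_short"


# ---------------------------------------------------------------------------
# assign / order / orient
# ---------------------------------------------------------------------------

def _toy_map(rows):
    df = pd.DataFrame(rows, columns=["marker", "group", "position_cM"])
    df["is_representative"] = True
    df["bin"] = df["marker"]
    return GeneticMap(df)


def test_majority_assignment_and_tie_rule():
    gmap = _toy_map(
        [("m1", "LG01", 0.0), ("m2", "LG01", 5.0), ("m3", "LG01", 9.0),
         ("m4", "LG02", 1.0), ("m5", "LG02", 2.0)]
    )
    markers = pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3", "m4", "m5"],
            "scaffold": ["sA", "sA", "sA", "sB", "sC"],
            "position": [100, 500, 900, 100, 100],
        }
    )
    assigned, unassigned = assign_scaffolds(markers, gmap)
    assert set(assigned.loc[assigned["scaffold"] == "sA", "group"]) == {"LG01"}
    # sB and sC each carry one mapped marker -> assigned to its group
    assert set(assigned["scaffold"]) == {"sA", "sB", "sC"}
    # a scaffold split 1:1 between groups is a tie
    markers_tie = pd.DataFrame(
        {"marker": ["m1", "m4"], "scaffold": ["sT", "sT"], "position": [1, 2]}
    )
    _, unassigned = assign_scaffolds(markers_tie, gmap)
    assert list(unassigned["scaffold"]) == ["sT"]
    assert list(unassigned["reason"]) == ["tie"]


def test_scaffolds_sort_by_mean_marker_cm():
    gmap = _toy_map(
        [("m1", "LG01", 10.0), ("m2", "LG01", 20.0), ("m3", "LG01", 5.0)]
    )
    markers = pd.DataFrame(
        {"marker": ["m1", "m2", "m3"], "scaffold": ["sA", "sA", "sB"],
         "position": [10, 20, 10]}
    )
    assigned, _ = assign_scaffolds(markers, gmap)
    placements = order_scaffolds(assigned, {"sA": 1000, "sB": 1000})
    assert list(placements["scaffold"]) == ["sB", "sA"]  # means 5 < 15
    assert list(placements["rank"]) == [1, 2]


def test_equal_means_break_ties_lexicographically():
    gmap = _toy_map([("m1", "LG01", 7.0), ("m2", "LG01", 7.0)])
    markers = pd.DataFrame(
        {"marker": ["m1", "m2"], "scaffold": ["sZ", "sA"], "position": [10, 10]}
    )
    assigned, _ = assign_scaffolds(markers, gmap)
    placements = order_scaffolds(assigned, {"sA": 1000, "sZ": 1000})
    assert list(placements["scaffold"]) == ["sA", "sZ"]


@pytest.mark.parametrize(
    "bp,cm,expected",
    [
        ((100, 500, 900), (1, 2, 3), ("+", True)),
        ((100, 500, 900), (3, 2, 1), ("-", True)),
        ((100,), (5,), ("+", False)),            # single marker: default
        ((100, 500), (2, 2), ("+", False)),       # tied cM: no information
        ((100, 500), (1, 2), ("+", True)),        # one informative pair decides
        ((1, 2, 3, 4), (2, 1, 4, 3), ("+", True)),
    ],
)
def test_orientation_rule(bp, cm, expected):
    assert orient_scaffold(bp, cm) == expected


def test_orientation_requires_a_marker():
    with pytest.raises(ValueError):
        orient_scaffold([], [])


@given(
    n=st.integers(min_value=1, max_value=8),
    data=st.data(),
)
@settings(max_examples=300, derandomize=True)
def test_orientation_matches_kendall_concordance_sign(n, data):
    """The orientation call equals the sign of the Kendall concordance
    (computed independently by scipy) over all marker configurations."""
    bp = data.draw(st.lists(st.integers(1, 10), min_size=n, max_size=n))
    cm = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    orientation, known = orient_scaffold(bp, cm)
    if n < 2 or len(set(bp)) < 2 or len(set(cm)) < 2:
        assert (orientation, known) == ("+", False)
        return
    tau = stats.kendalltau(bp, cm).statistic
    if np.isnan(tau) or tau == 0:
        assert (orientation, known) == ("+", False)
    elif tau > 0:
        assert (orientation, known) == ("+", True)
    else:
        assert (orientation, known) == ("-", True)


def test_reflection_symmetry_flips_orientations_and_ranks():
    """Negating every cM position reverses ranks and flips known orientations."""
    gmap = _toy_map(
        [("m1", "LG01", 0.0), ("m2", "LG01", 10.0), ("m3", "LG01", 20.0),
         ("m4", "LG01", 30.0)]
    )
    markers = pd.DataFrame(
        {"marker": ["m1", "m2", "m3", "m4"],
         "scaffold": ["sA", "sA", "sB", "sB"],
         "position": [100, 900, 900, 100]}
    )
    lengths = {"sA": 1000, "sB": 1000}
    assigned, _ = assign_scaffolds(markers, gmap)
    fwd = order_scaffolds(assigned, lengths)
    mirrored = gmap.positions.copy()
    mirrored["position_cM"] = -mirrored["position_cM"]
    assigned_m, _ = assign_scaffolds(markers, GeneticMap(mirrored))
    rev = order_scaffolds(assigned_m, lengths)
    f = fwd.set_index("scaffold")
    m = rev.set_index("scaffold")
    n = len(f)
    for s in f.index:
        assert m.loc[s, "rank"] == n + 1 - f.loc[s, "rank"]
        if f.loc[s, "orientation_known"]:
            assert m.loc[s, "orientation"] != f.loc[s, "orientation"]


# ---------------------------------------------------------------------------
# Pseudomolecule assembly
# ---------------------------------------------------------------------------

def _placements(rows):
    df = pd.DataFrame(
        rows,
        columns=["scaffold", "chromosome", "rank", "orientation",
                 "orientation_known", "mean_cM", "n_markers", "length", "offset"],
    )
    return df


def test_pseudomolecule_arithmetic_and_offsets():
    seqs = {f"s{i}": "ACGT" * 250 for i in range(1, 4)}  # 1000 bp each
    pl = _placements(
        [(f"s{i}", "LG01", i, "+", True, i * 10.0, 2, 1000, pd.NA) for i in (1, 2, 3)]
    )
    chroms, agp, placed = build_pseudomolecules(seqs, pl, gap_bp=100)
    assert len(chroms["LG01"]) == 3200
    assert list(placed["offset"]) == [1, 1101, 2201]
    # AGP rows tile [1, 3200] exactly, W alternating with U
    assert list(agp["component_type"]) == ["W", "U", "W", "U", "W"]
    assert agp.iloc[0]["object_beg"] == 1
    assert agp.iloc[-1]["object_end"] == 3200
    for prev, nxt in zip(agp.itertuples(index=False), agp.iloc[1:].itertuples(index=False)):
        assert nxt.object_beg == prev.object_end + 1


def test_minus_scaffold_is_reverse_complemented():
    seq = "AACCGGTTAACCGGTTAACG"
    pl = _placements([("s1", "LG01", 1, "-", True, 0.0, 1, len(seq), pd.NA)])
    chroms, _, _ = build_pseudomolecules({"s1": seq}, pl, gap_bp=100)
    assert chroms["LG01"] == revcomp(seq)


def test_duplicate_scaffold_rejected():
    pl = _placements(
        [("s1", "LG01", 1, "+", True, 0.0, 1, 4, pd.NA),
         ("s1", "LG01", 2, "+", True, 1.0, 1, 4, pd.NA)]
    )
    with pytest.raises(ValueError, match="s1"):
        build_pseudomolecules({"s1": "ACGT"}, pl)


def test_agp_round_trip(tmp_path):
    seqs = {"s1": "A" * 1000, "s2": "C" * 2000}
    pl = _placements(
        [("s1", "LG01", 1, "+", True, 0.0, 1, 1000, pd.NA),
         ("s2", "LG01", 2, "-", True, 5.0, 1, 2000, pd.NA)]
    )
    _, agp, _ = build_pseudomolecules(seqs, pl, gap_bp=50)
    path = tmp_path / "test.agp"
    write_agp(agp, path)
    again = read_agp(path)
    assert len(again) == 3
    assert list(again["component_type"]) == ["W", "U", "W"]


def test_noiseless_small_genome_fully_recovered(clean_ds):
    from mapanchor import score_scaffold_recovery

    retained, _ = filter_markers(clean_ds.genotypes)
    gmap = build_map(retained, prefiltered=True)
    assigned, _ = assign_scaffolds(clean_ds.genotypes.markers, gmap)
    placements = order_scaffolds(
        assigned, {s: len(q) for s, q in clean_ds.scaffolds.items()}
    )
    score = score_scaffold_recovery(placements, clean_ds.truth)
    assert score["frac_assigned"] == 1.0
    assert score["frac_ordered"] == 1.0
    assert score["frac_decided_orientation_correct"] == 1.0
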