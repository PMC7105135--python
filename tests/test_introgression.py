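"""Introgression mapper: filters, origin rules, block chaining vs an
exhaustive oracle, masking, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wolbmeth import introgression as intro


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele", "zygosity",
                                       "depth", "quality"])


def _origins(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "origin"])


@pytest.mark.parametrize("zyg,depth,qual,kept", [
    ("hom", 10, 30, True),    # at both thresholds: retained
    ("het", 50, 40, False),   # heterozygous always removed
    ("hom", 100, 29, False),  # quality just below threshold
    ("hom", 9, 90, False),
])
def test_filter_thresholds(zyg, depth, qual, kept):
    out = intro.filter_snp_calls(_calls([("chr1", 100, "A", zyg, depth, qual)]))
    assert (len(out) == 1) == kept


def test_classify_origin_exhaustive_alleles():
    """All four observed alleles against a fixed panel row: the allele must
    equal the maternal or paternal base to be classified."""
    panel = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                          "maternal_allele": ["A"], "paternal_allele": ["G"]})
    for allele, expected in [("A", "maternal"), ("G", "paternal"),
                             ("T", "unclassified"), ("C", "unclassified")]:
        out = intro.classify_origin(_calls([("chr1", 100, allele, "hom", 30, 40)]), panel)
        assert out["origin"].iloc[0] == expected
    # position absent from panel
    out = intro.classify_origin(_calls([("chr1", 999, "A", "hom", 30, 40)]), panel)
    assert out["origin"].iloc[0] == "unclassified"


def test_classify_origin_duplicate_panel_rejected():
    panel = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 100],
                          "maternal_allele": ["A", "A"], "paternal_allele": ["G", "C"]})
    with pytest.raises(ValueError, match="duplicate"):
        intro.classify_origin(_calls([("chr1", 100, "A", "hom", 30, 40)]), panel)


def _oracle_blocks(origins: pd.DataFrame, threshold: int) -> list:
    """Independent chaining oracle: adjacent maternal SNPs (in the
    informative ordering) are linked iff their gap is <= threshold and no
    paternal SNP lies strictly between; blocks are connected components."""
    blocks = []
    for chrom, sub in origins[origins["origin"] != "unclassified"].groupby("chrom"):
        sub = sub.sort_values("pos")
        mats = sub.loc[sub["origin"] == "maternal", "pos"].tolist()
        pats = sub.loc[sub["origin"] == "paternal", "pos"].tolist()
        comp = []
        for pos in mats:
            linked = (comp
                      and pos - comp[-1] <= threshold
                      and not any(comp[-1] < p < pos for p in pats))
            if linked:
                comp.append(pos)
            else:
                if comp:
                    blocks.append((chrom, comp[0], comp[-1], len(comp)))
                comp = [pos]
        if comp:
            blocks.append((chrom, comp[0], comp[-1], len(comp)))
    return sorted(blocks)


@pytest.mark.parametrize("positions,origins,expected", [
    # one chain of three within threshold
    ([1000, 5000, 9000], ["maternal"] * 3, [("chr1", 1000, 9000, 3)]),
    # gap beyond threshold: two singleton blocks
    ([1000, 20000], ["maternal"] * 2, [("chr1", 1000, 1000, 1), ("chr1", 20000, 20000, 1)]),
    # paternal SNP breaks the chain even within distance
    ([1000, 3000, 5000], ["maternal", "paternal", "maternal"],
     [("chr1", 1000, 1000, 1), ("chr1", 5000, 5000, 1)]),
    # unclassified neither breaks nor extends
    ([1000, 3000, 5000], ["maternal", "unclassified", "maternal"],
     [("chr1", 1000, 5000, 2)]),
])
def test_chaining_examples(positions, origins, expected):
    df = _origins([("chr1", p, o) for p, o in zip(positions, origins)])
    out = intro.call_maternal_blocks(df, threshold=10_000)
    got = sorted(map(tuple, out.to_records(index=False)))
    assert got == expected
    assert got == _oracle_blocks(df, 10_000)


def test_threshold_must_be_positive():
    with pytest.raises(ValueError):
        intro.call_maternal_blocks(_origins([]), threshold=0)


@settings(max_examples=300, deadline=None)
@given(st.data())
def test_chaining_matches_oracle_on_random_inputs(data):
    n = data.draw(st.integers(0, 20))
    pos = sorted(data.draw(st.sets(st.integers(1, 50_000), min_size=n, max_size=n)))
    origins = [data.draw(st.sampled_from(["maternal", "paternal", "unclassified"]))
               for _ in pos]
    threshold = data.draw(st.sampled_from([500, 2_000, 10_000]))
    df = _origins([("chr1", p, o) for p, o in zip(pos, origins)])
    out = intro.call_maternal_blocks(df, threshold)
    assert sorted(map(tuple, out.to_records(index=False))) == _oracle_blocks(df, threshold)


def test_chaining_order_independent():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(100_000, 200, replace=False)) + 1
    orig = rng.choice(["maternal", "paternal", "unclassified"], 200)
    df = _origins([("chr1", p, o) for p, o in zip(pos, orig)])
    shuffled = df.sample(frac=1.0, random_state=1)
    a = intro.call_maternal_blocks(df, 2_000)
    b = intro.call_maternal_blocks(shuffled, 2_000)
    pd.testing.assert_frame_equal(a, b)


def test_chaining_threshold_monotonicity():
    rng = np.random.default_rng(3)
    pos = np.sort(rng.choice(200_000, 300, replace=False)) + 1
    orig = rng.choice(["maternal", "paternal"], 300, p=[0.7, 0.3])
    df = _origins([("chr1", p, o) for p, o in zip(pos, orig)])
    prev_count, prev_bp = None, None
    for thr in (500, 2_000, 10_000, 50_000):
        blocks = intro.call_maternal_blocks(df, thr)
        bp = int((blocks["end"] - blocks["start"] + 1).sum())
        if prev_count is not None:
            assert len(blocks) <= prev_count
            assert bp >= prev_bp
        prev_count, prev_bp = len(blocks), bp


def test_mask_intervals_matches_bruteforce():
    rng = np.random.default_rng(1)
    sites = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 100_000, 1_000)})
    blocks = pd.DataFrame({"chrom": ["chr1"] * 3,
                           "start": [1_000, 40_000, 90_000],
                           "end": [9_000, 41_000, 99_999]})
    kept, summary = intro.mask_intervals(blocks, sites)
    brute = sites[~sites["pos"].apply(
        lambda p: any(s <= p <= e for s, e in zip(blocks["start"], blocks["end"])))]
    assert kept["pos"].tolist() == brute["pos"].tolist()
    assert summary["n_masked_sites"] == len(sites) - len(brute)


def test_mask_boundary_inclusive_and_empty_blocks():
    sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [999, 1_000, 9_000]})
    blocks = pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [9_000]})
    kept, _ = intro.mask_intervals(blocks, sites)
    assert kept["pos"].tolist() == [999]
    kept_all, summary = intro.mask_intervals(blocks.iloc[0:0], sites)
    assert len(kept_all) == len(sites) and summary["n_masked_sites"] == 0


def test_bed_round_trip():
    blocks = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [1_000, 1],
                           "end": [9_000, 500]})
    bed = intro.blocks_to_bed(blocks)
    assert bed["start"].tolist() == [999, 0]
    assert bed["end"].tolist() == [9_000, 500]


def test_summary_adjacent_distances():
    df = _origins([("chr1", p, "maternal") for p in (1_000, 2_000, 4_000)])
    blocks = intro.call_maternal_blocks(df, 10_000)
    s = intro.summarize_introgression(df, blocks, genome_size=1_000_000)
    assert s["n_adjacent_distances"] == 2
    assert s["frac_adjacent_within_2kb"] == 1.0
    assert s["n_maternal_snps"] == 3


def test_summary_maternal_fraction():
    blocks = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [50_000]})
    s = intro.summarize_introgression(_origins([]), blocks, genome_size=1_000_000)
    assert s["maternal_fraction"] == pytest.approx(0.05)
    assert np.isnan(s["frac_adjacent_within_2kb"])


def test_summary_rejects_bad_genome_size():
    with pytest.raises(ValueError):
        intro.summarize_introgression(_origins([]), pd.DataFrame(), genome_size=0)
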