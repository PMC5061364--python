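import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventpop import diversity as dv
from ventpop.io_align import (CodonAlignment, PopulationSample, SequenceRecord,
                              complete_sites)
from ventpop.synthetic_data import SynthConfig, simulate_alignment


# --- independent brute-force oracles (pure-python, no shared code paths) ---

def oracle_pi(seqs):
    pairs = list(itertools.combinations(seqs, 2))
    total = 0.0
    for a, b in pairs:
        total += sum(x != y for x, y in zip(a, b)) / len(a)
    return total / len(pairs)


def oracle_s(seqs):
    return sum(1 for col in zip(*seqs) if len(set(col)) > 1)


def oracle_hd(seqs):
    n = len(seqs)
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return n * (1 - sum((c / n) ** 2 for c in counts.values())) / (n - 1)


def _pop(seqs):
    aln = CodonAlignment(
        [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]
    )
    return PopulationSample(aln, complete_sites(aln, aln.ids()))


def test_oracle_equivalence_on_fixtures(tajima_toy, mono):
    for pop, _ in (tajima_toy, mono):
        seqs = pop.masked_seqs()
        assert dv.segregating_sites(pop) == oracle_s(seqs)
        assert dv.haplotype_diversity(pop) == pytest.approx(oracle_hd(seqs))
        assert dv.nucleotide_diversity(pop, "none") == pytest.approx(
            oracle_pi(seqs)
        )


def test_oracle_equivalence_on_simulated_samples():
    for seed in range(6):
        cfg = SynthConfig(n=8, L=60, theta=4.0, seed=seed)
        aln = simulate_alignment(cfg)
        pop = PopulationSample(aln, complete_sites(aln, aln.ids()))
        seqs = pop.masked_seqs()
        assert dv.segregating_sites(pop) == oracle_s(seqs)
        assert dv.collapse_haplotypes(pop).n_hap == len(set(seqs))
        assert dv.nucleotide_diversity(pop, "none") == pytest.approx(
            oracle_pi(seqs)
        )
        assert dv.haplotype_diversity(pop) == pytest.approx(oracle_hd(seqs))


def test_collapse_haplotypes_counts_and_localities():
    recs = [
        SequenceRecord("a", "AAA", site="S1"),
        SequenceRecord("b", "AAA", site="S2"),
        SequenceRecord("c", "AAA", site="S2"),
        SequenceRecord("d", "AAT", site="S1"),
    ]
    aln = CodonAlignment(recs)
    pop = PopulationSample(aln, complete_sites(aln, aln.ids()))
    table = dv.collapse_haplotypes(pop)
    assert table.n_hap == 2
    assert table.counts == [3, 1]
    assert table.locality_counts[0] == {"S1": 1, "S2": 2}
    assert table.n_seq == 4


def test_haplotype_diversity_extremes():
    assert dv.haplotype_diversity(["AAA"] * 5) == 0.0
    assert dv.haplotype_diversity(["AAA", "AAT", "ATT", "TTT"]) == 1.0
    assert dv.haplotype_diversity(["AAA", "AAA", "AAT", "AAT"]) == pytest.approx(2 / 3)


@settings(deadline=None, derandomize=True)
@given(st.permutations(list(range(6))))
def test_statistics_invariant_to_sequence_order(perm):
    seqs = ["ACGT", "ACGA", "ACTT", "ACGT", "TCGT", "ACGC"]
    shuffled = [seqs[i] for i in perm]
    assert dv.haplotype_diversity(shuffled) == pytest.approx(
        dv.haplotype_diversity(seqs)
    )
    assert dv.segregating_sites(shuffled) == dv.segregating_sites(seqs)
    assert dv.nucleotide_diversity(shuffled, "none") == pytest.approx(
        dv.nucleotide_diversity(seqs, "none")
    )


def test_jukes_cantor_closed_form():
    # 1 difference over 100 sites
    seqs = ["A" * 100, "T" + "A" * 99]
    assert dv.nucleotide_diversity(seqs, "none") == pytest.approx(0.01)
    assert dv.nucleotide_diversity(seqs, "JC") == pytest.approx(
        -0.75 * math.log(1 - 0.04 / 3)
    )


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=0.74))
def test_jc_correction_exceeds_p(p):
    assert dv.jukes_cantor(p) > p


def test_jc_undefined_at_saturation():
    with pytest.raises(ValueError, match="0.75"):
        dv.jukes_cantor(0.8)
    seqs = ["AAAA", "TTTT"]
    with pytest.raises(ValueError, match="pair"):
        dv.nucleotide_diversity(seqs, "JC")


def test_monomorphic_diversity_is_zero(mono):
    pop, _ = mono
    assert dv.nucleotide_diversity(pop, "none") == 0.0
    assert dv.nucleotide_diversity(pop, "JC") == 0.0


# --- synonymous/nonsynonymous decomposition ---

def test_fourfold_third_position_change_is_synonymous():
    # GGA -> GGG is synonymous (Gly 4-fold); pi_a = 0, ratio reported 0
    pop = _pop(["GGAGGA", "GGGGGA"])
    pa, ps, ratio = dv.pi_syn_nonsyn(pop)
    assert pa == 0.0 and ps > 0.0 and ratio == 0.0


def test_first_position_nonsynonymous_change():
    # GCA (Ala) -> CCA (Pro): nonsynonymous only
    pop = _pop(["GCAGCA", "CCAGCA"])
    pa, ps, ratio = dv.pi_syn_nonsyn(pop)
    assert ps == 0.0 and pa > 0.0 and ratio == math.inf


def test_identical_sequences_have_undefined_ratio():
    pop = _pop(["GCAGCA", "GCAGCA"])
    pa, ps, ratio = dv.pi_syn_nonsyn(pop)
    assert pa == 0.0 and ps == 0.0 and ratio is None


def test_pi_syn_nonsyn_requires_codon_mask():
    aln = CodonAlignment(
        [SequenceRecord("a", "NNGCA"), SequenceRecord("b", "NNGCA")]
    )
    pop = PopulationSample(aln, complete_sites(aln, aln.ids()))
    with pytest.raises(ValueError, match="codon"):
        dv.pi_syn_nonsyn(pop)


# --- p-distances ---

def test_p_distance_identical_group():
    df = dv.p_distance_summary({"g": ["ACGT" * 5] * 4}, bootstrap_reps=50,
                               seed=0)
    row = df.iloc[0]
    assert row.within_mean == 0.0 and row.within_SE == 0.0


def test_p_distance_between_groups_single_pair():
    a = "A" * 10
    b = "T" * 2 + "A" * 8  # 20% divergent
    df = dv.p_distance_summary({"g1": [a], "g2": [b]}, bootstrap_reps=10,
                               seed=0)
    assert df.set_index("group").loc["g1", "between_min"] == pytest.approx(0.2)
    assert np.isnan(df.set_index("group").loc["g1", "within_mean"])


def test_p_distance_pairwise_deletion():
    # N column ignored for the pair that has it
    df = dv.p_distance_summary(
        {"g": ["ACGTA", "ACGTN", "TCGTA"]}, bootstrap_reps=5, seed=1
    )
    row = df.iloc[0]
    # pairs: (1,2): 0/4; (1,3): 1/5; (2,3): 1/4
    assert row.within_mean == pytest.approx((0 + 0.2 + 0.25) / 3)


def test_diversity_table_marks_excluded_population():
    aln = CodonAlignment(
        [SequenceRecord("a", "ACGTAA", site="X"),
         SequenceRecord("b", "ACGTAT", site="X")]
    )
    pop = PopulationSample(aln, complete_sites(aln, aln.ids()),
                           species="sp", site="X", excluded=True)
    table = dv.diversity_table([dv.diversity_summary(pop)])
    row = table.iloc[0]
    assert row["Hd"] == "-" and row["S"] == "-" and row["N_Seq"] == 2
    assert row["N_Hap"] == "2"
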