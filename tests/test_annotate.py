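import math

import numpy as np
import pytest

from metatriage.annotate import (
    AnnotationCall,
    ScoringScheme,
    Tier,
    TierConfig,
    cascade_annotate,
    compute_max_bitscore,
    pmpb,
    resolve_description,
    select_annotation,
    taxonomic_rollup,
)
from metatriage.core import HitRecord, Lineage


def hit(q="c1", s="P1", evalue=1e-50, bitscore=100.0, desc="protein X", taxon="taxA", tier=1):
    return HitRecord(q, s, 90.0, 100, evalue, bitscore, desc, taxon, tier)


# ---------------------------------------------------------------------------
# max bitscore / PMPB

def test_max_bitscore_closed_form_hand_computed():
    scheme = ScoringScheme("toy", {"A": 4}, lam=0.3176, k=0.134)
    # 10 alanines: raw 40, bits = (0.3176*40 - ln 0.134)/ln 2
    expected = (0.3176 * 40 - math.log(0.134)) / math.log(2)
    assert compute_max_bitscore("A" * 10, scheme) == pytest.approx(expected)
    assert expected == pytest.approx(21.23, abs=0.01)


def test_max_bitscore_monotone_in_length_and_blosum_diagonal():
    scheme = ScoringScheme.blosum62_ungapped()
    assert scheme.diagonal["A"] == 4  # BLOSUM62 self score for Ala
    b1 = compute_max_bitscore("MKV", scheme)
    b2 = compute_max_bitscore("MKVMKV", scheme)
    assert b2 > b1 > 0


def test_max_bitscore_errors():
    scheme = ScoringScheme("toy", {"A": 4}, lam=0.3, k=0.1)
    with pytest.raises(ValueError):
        compute_max_bitscore("", scheme)
    with pytest.raises(ValueError, match="'B'"):
        compute_max_bitscore("AB", scheme)


def test_pmpb_values_and_cap():
    assert pmpb(80, 100) == 80.0
    assert pmpb(250.0, 250.0) == 100.0
    with pytest.warns(UserWarning, match="capped"):
        assert pmpb(105, 100) == 100.0
    with pytest.raises(ValueError):
        pmpb(50, 0)


# ---------------------------------------------------------------------------
# selection: brute-force oracle

def selector_oracle(hits, self_score, cutoff, window):
    """Literal application of the stated rules: drop e-value >= cutoff,
    primary = max PMPB with (evalue, tier, subject) tie-break, secondary
    = within window, best hit per subject, primary's subject excluded."""
    alive = [h for h in hits if h.evalue < cutoff]
    if not alive:
        return None
    def p(h):
        return min(100.0 * h.bitscore / self_score, 100.0)
    def key(h):
        return (-p(h), h.evalue, h.db_tier, h.subject_id)
    primary = min(alive, key=key)
    secondaries = {}
    for h in alive:
        if h.subject_id == primary.subject_id:
            continue
        if p(h) < p(primary) - window:
            continue
        if h.subject_id not in secondaries or key(h) < key(secondaries[h.subject_id]):
            secondaries[h.subject_id] = h
    return primary, set(secondaries.values())


def random_hit_table(rng, query="c1"):
    n = rng.integers(1, 20)
    subjects = [f"S{rng.integers(1, 12)}" for _ in range(n)]
    return [
        HitRecord(
            query,
            subj,
            float(np.round(rng.uniform(20, 100), 1)),
            int(rng.integers(30, 400)),
            float(10.0 ** rng.uniform(-80, 0)),
            float(np.round(rng.uniform(5, 120), 1)),
            "desc",
            "taxA",
            int(rng.integers(1, 5)),
        )
        for subj in subjects
    ]


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.filterwarnings("ignore:hit bitscore")
def test_select_annotation_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    tier = Tier(1, 1e-4)
    for _ in range(60):
        hits = random_hit_table(rng)
        self_score = float(rng.uniform(100, 150))
        expected = selector_oracle(hits, self_score, tier.evalue_cutoff, 10.0)
        got = select_annotation(hits, self_score, tier, 10.0)
        if expected is None:
            assert got is None
            continue
        (primary, _pp), secondary = got
        exp_primary, exp_secondary = expected
        assert primary == exp_primary
        assert {h for h, _ in secondary} == exp_secondary


def test_selection_examples_and_tie_breaks():
    tier = Tier(1, 1e-4)
    hits = [
        hit(s="P1", bitscore=95.0),
        hit(s="P2", bitscore=90.0),
        hit(s="P3", bitscore=70.0),
    ]
    (primary, pp), secondary = select_annotation(hits, 100.0, tier, 10.0)
    assert primary.subject_id == "P1" and pp == 95.0
    assert [h.subject_id for h, _ in secondary] == ["P2"]

    tie = [hit(s="Pa", bitscore=95.0, evalue=1e-40), hit(s="Pb", bitscore=95.0, evalue=1e-50)]
    (primary, _), _sec = select_annotation(tie, 100.0, tier, 10.0)
    assert primary.subject_id == "Pb"  # lower e-value wins the PMPB tie

    dead = [hit(evalue=1e-3), hit(s="P2", evalue=2e-4)]
    assert select_annotation(dead, 100.0, tier, 10.0) is None

    with pytest.raises(ValueError, match="self-score"):
        select_annotation([hit()], 0.0, tier)


def test_window_monotonicity():
    rng = np.random.default_rng(42)
    tier = Tier(1, 1e-4)
    for _ in range(30):
        hits = random_hit_table(rng)
        sel_small = select_annotation(hits, 120.0, tier, 5.0)
        sel_large = select_annotation(hits, 120.0, tier, 15.0)
        if sel_small is None:
            assert sel_large is None
            continue
        small = {h.subject_id for h, _ in sel_small[1]}
        large = {h.subject_id for h, _ in sel_large[1]}
        assert small <= large


# ---------------------------------------------------------------------------
# cascade

def cascade_fixture():
    tiers = (Tier(1, 1e-4, "protein", "all"), Tier(2, 1e-4, "protein", "de_only"),
             Tier(3, 1e-6, "nucleotide", "de_only"))
    config = TierConfig(tiers=tiers)
    hits = {
        1: [hit(q="cA", s="T1", bitscore=60.0, tier=1)],
        2: [hit(q="cB", s="T2", bitscore=80.0, tier=2)],
        3: [hit(q="cA", s="T3", bitscore=99.0, tier=3, evalue=1e-20),
            hit(q="cC", s="T3c", bitscore=90.0, tier=3, evalue=1e-20)],
    }
    scores = {"cA": 100.0, "cB": 100.0, "cC": 100.0, "cD": 100.0}
    return config, hits, scores


def test_cascade_earlier_tier_wins_and_de_only_scoping():
    config, hits, scores = cascade_fixture()
    de = {"cA": True, "cB": True, "cC": True, "cD": False}
    calls = cascade_annotate(["cA", "cB", "cC", "cD"], hits, scores, config, de)
    assert calls["cA"].tier == 1  # tier-3 hit scores higher but loses precedence
    assert calls["cA"].primary.subject_id == "T1"
    assert calls["cB"].tier == 2  # DE contig falls through to the fallback tier
    assert calls["cC"].tier == 3
    assert calls["cD"].status == "unknown"  # non-DE contig never sees tiers 2-3


# ---------------------------------------------------------------------------
# description demotion

def call_with(primary_desc, secondary_specs):
    primary = hit(s="P0", bitscore=95.0, desc=primary_desc, taxon="taxP")
    secondary = [
        (hit(s=f"S{i}", bitscore=b, desc=d, taxon=f"tax{i}"), b)
        for i, (b, d) in enumerate(secondary_specs)
    ]
    return AnnotationCall(
        contig_id="c1", status="annotated", tier=1, primary=primary,
        primary_pmpb=95.0, secondary=secondary,
        resolved_description=primary_desc,
    )


def test_demotion_promotes_best_informative_secondary():
    call = call_with(
        "hypothetical protein",
        [(92.0, "Monosaccharide transporter"), (94.0, "predicted protein")],
    )
    out = resolve_description(call)
    assert out.demoted
    assert out.resolved_description == "Monosaccharide transporter"
    assert out.primary.subject_id == "S0"
    assert out.primary.subject_taxon == "tax0"  # taxon of record follows the swap
    assert {h.subject_id for h, _ in out.secondary} == {"P0", "S1"}


def test_demotion_no_ops():
    informative = call_with("ATP synthase", [(94.0, "hypothetical protein")])
    assert not resolve_description(informative).demoted
    hopeless = call_with("hypothetical protein", [(94.0, "uncharacterised protein")])
    out = resolve_description(hopeless)
    assert not out.demoted
    assert out.resolved_description == "hypothetical protein"


# ---------------------------------------------------------------------------
# rollup

def test_rollup_additivity_and_fallbacks():
    taxonomy = {
        "tx_bas": Lineage.parse("kingdom:Fungi;phylum:Basidiomycota;genus:X"),
        "tx_asc": Lineage.parse("kingdom:Fungi;phylum:Ascomycota;genus:Y"),
    }
    calls = {}
    for i in range(3):
        calls[f"b{i}"] = AnnotationCall(
            f"b{i}", "annotated", 1, hit(q=f"b{i}", taxon="tx_bas"), 90.0
        )
    calls["a0"] = AnnotationCall("a0", "annotated", 1, hit(q="a0", taxon="tx_asc"), 90.0)
    calls["weird"] = AnnotationCall(
        "weird", "annotated", 1, hit(q="weird", taxon="tx_missing"), 90.0
    )
    calls["dark"] = AnnotationCall("dark", "unknown")
    tpm = {cid: 10.0 for cid in calls}
    root = taxonomic_rollup(calls, taxonomy, tpm)
    assert root.n_contigs == 6
    fungi = root.children["Fungi"]
    assert fungi.n_contigs == 4
    assert fungi.children["Basidiomycota"].n_contigs == 3
    assert root.children["unclassified"].n_contigs == 1
    assert root.children["Unknown"].n_contigs == 1
    # conservation: every node equals the sum of its children plus terminals
    for _path, node in root.walk():
        child_sum = sum(c.n_contigs for c in node.children.values())
        assert node.n_contigs >= child_sum
        child_tpm = sum(c.total_tpm for c in node.children.values())
        assert node.total_tpm >= child_tpm - 1e-9
    assert root.total_tpm == pytest.approx(60.0)


def test_rollup_recovers_generator_kingdom_counts(scenario, scenario_calls):
    root = taxonomic_rollup(scenario_calls, scenario.taxonomy, {})
    truth_by_kingdom = {}
    for cid, t in scenario.truth.contigs.items():
        call = scenario_calls[cid]
        if call.status != "annotated" or call.primary.subject_id != t.intended_primary:
            continue
        kingdom = scenario.taxonomy[t.taxon_key].name_at("kingdom")
        truth_by_kingdom[kingdom] = truth_by_kingdom.get(kingdom, 0) + 1
    for sk in root.children.values():
        for name, node in sk.children.items():
            if name in truth_by_kingdom:
                assert node.n_contigs == truth_by_kingdom[name]
    assert root.n_contigs == len(scenario.truth.contigs)
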