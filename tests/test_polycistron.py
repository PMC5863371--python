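import numpy as np
import pytest
from Bio.Seq import Seq

from metatriage.core import OperonReference
from metatriage.polycistron import (
    HexamerModel,
    OrfCall,
    build_operon,
    find_orfs,
    flag_duplicates,
)

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# brute-force 6-frame oracle (literal restatement of the extraction rules)

def orf_oracle(seq, min_aa=100, require_start=True, allow_edge_partials=True):
    found = set()
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            codons = []
            pos = frame
            while pos + 3 <= len(s):
                codons.append(s[pos : pos + 3])
                pos += 3
            # stop positions in codon space
            stops = [i for i, c in enumerate(codons) if c in STOPS and "N" not in c]
            bounds = [-1] + stops + [len(codons)]
            for b in range(len(bounds) - 1):
                lo, hi = bounds[b] + 1, bounds[b + 1]  # segment codons [lo, hi)
                if hi == len(codons) and bounds[b + 1] not in stops:
                    closed = False
                else:
                    closed = hi < len(codons) or bounds[b + 1] in stops
                closed = bounds[b + 1] != len(codons)
                if lo == 0 and allow_edge_partials:
                    start = lo
                elif require_start:
                    atgs = [i for i in range(lo, hi) if codons[i] == "ATG" and "N" not in codons[i]]
                    if not atgs:
                        continue
                    start = atgs[0]
                else:
                    start = lo
                if closed:
                    n_aa = hi - start
                    end_codon = hi + 1
                else:
                    if not allow_edge_partials:
                        continue
                    n_aa = hi - start
                    end_codon = hi
                if n_aa < min_aa:
                    continue
                a = frame + 3 * start
                e = frame + 3 * end_codon
                if strand == "+":
                    found.add((a, e, "+"))
                else:
                    found.add((L - e, L - a, "-"))
    return found


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_basic_complete_orf():
    seq = "ATG" + "GCT" * 99 + "TAA"
    orfs = find_orfs("c1", seq, min_aa=100, allow_edge_partials=False)
    assert len(orfs) == 1
    orf = orfs[0]
    assert (orf.start, orf.end, orf.strand) == (0, 303, "+")
    assert not orf.partial5 and not orf.partial3
    assert orf.aa_sequence == "M" + "A" * 99
    assert len(orf.aa_sequence) == 100


def test_reverse_complement_mirrors_coordinates():
    seq = "ATG" + "GCT" * 99 + "TAA"
    rc = str(Seq(seq).reverse_complement())
    orfs = find_orfs("c1", rc, min_aa=100, allow_edge_partials=False)
    assert len(orfs) == 1
    orf = orfs[0]
    assert (orf.start, orf.end, orf.strand) == (0, 303, "-")
    assert orf.aa_sequence == "M" + "A" * 99


@pytest.mark.parametrize("seed", range(6))
def test_find_orfs_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        seq = random_seq(rng, int(rng.integers(300, 3000)))
        for min_aa, req, edge in ((30, True, True), (30, True, False), (50, False, True)):
            got = {
                (o.start, o.end, o.strand)
                for o in find_orfs("c", seq, min_aa=min_aa, require_start=req,
                                   allow_edge_partials=edge)
            }
            assert got == orf_oracle(seq, min_aa, req, edge)


def test_strand_symmetry_property():
    rng = np.random.default_rng(99)
    for _ in range(20):
        seq = random_seq(rng, 1200)
        rc = str(Seq(seq).reverse_complement())
        fwd = {(o.start, o.end, o.strand, o.aa_sequence) for o in find_orfs("c", seq, min_aa=30)}
        mirrored = {
            (len(seq) - e, len(seq) - s, "+" if st == "-" else "-", aa)
            for s, e, st, aa in fwd
        }
        rev = {(o.start, o.end, o.strand, o.aa_sequence) for o in find_orfs("c", rc, min_aa=30)}
        assert rev == mirrored


def test_n_codons_never_start_or_stop():
    seq = "ATN" + "GCT" * 40 + "TAN" + "GCT" * 5 + "TAA"
    orfs = find_orfs("c", seq, min_aa=10, allow_edge_partials=True, require_start=False)
    # no internal stop is recognised at the TAN codon
    assert all("TAN" not in (o.start, o.end) for o in orfs)
    with pytest.raises(ValueError, match="non-ACGTN"):
        find_orfs("c", "ATGXXX")


def test_orfcall_invariants_enforced():
    with pytest.raises(ValueError, match="whole number of codons"):
        OrfCall("c", 0, 100, "+", 0, "M" * 33)
    with pytest.raises(ValueError, match="inconsistent"):
        OrfCall("c", 0, 303, "+", 0, "M" * 50)


# ---------------------------------------------------------------------------
# hexamer coding score

def make_coding_sampler(seed=0, concentration=10.0):
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    probs = rng.dirichlet(np.full(64, concentration))
    return rng, lambda n, r: "".join(r.choice(codons, size=n, p=probs))


def test_hexamer_model_separates_coding_from_random():
    rng, draw = make_coding_sampler()
    model = HexamerModel().train([draw(500, rng) for _ in range(20)], seed=1)
    coding = [model.score(draw(150, rng)) for _ in range(100)]
    uniform = [model.score(random_seq(rng, 450)) for _ in range(100)]
    se_c = np.std(coding) / 10
    assert np.mean(coding) > 3 * se_c  # coding draws score clearly positive
    # uniform sequences sit near zero (small negative bias from the more
    # concentrated coding hexamer distribution), far below the coding signal
    assert abs(np.mean(uniform)) < np.mean(coding) / 2
    assert np.mean(uniform) < np.mean(coding) - 3 * se_c


def test_hexamer_model_guards():
    model = HexamerModel()
    with pytest.raises(ValueError, match="not trained"):
        model.score("ACGTACGT")
    with pytest.raises(ValueError, match="10 kb"):
        model.train(["ACGTAC"])
    trained = HexamerModel().train(["ACGT" * 3000], seed=0)
    with pytest.raises(ValueError, match="hexamer"):
        trained.score("ACG")


# ---------------------------------------------------------------------------
# operons

def orf_at(start, symbol, strand="+", n_aa=100, contig="cX"):
    aa = "M" + "A" * (n_aa - 1)
    return OrfCall(contig, start, start + 3 * (n_aa + 1), strand, 0, aa,
                   gene_symbol=symbol)


@pytest.fixture
def reference():
    return OperonReference(
        {"opr_alk": ("yojI", "alkB", "ada", "apbE", "mqo"),
         "opr_tau": ("tauA", "tauB")}
    )


def test_build_operon_exact_chain(reference):
    orfs = [orf_at(1000 * i, g) for i, g in enumerate(["yojI", "alkB", "ada", "apbE", "mqo"])]
    (call,) = build_operon(orfs, reference)
    assert call.chain == "yojI-alkB-ada-apbE-mqo"
    assert call.match_status == "exact"
    assert call.matched_operon_id == "opr_alk"


def test_build_operon_contiguous_subset_and_novel(reference):
    orfs = [orf_at(1000 * i, g) for i, g in enumerate(["yojI", "alkB", "ada", "apbE"])]
    (call,) = build_operon(orfs, reference)
    assert call.match_status == "contiguous_subset"
    assert call.matched_operon_id == "opr_alk"
    shuffled = [orf_at(1000 * i, g) for i, g in enumerate(["ada", "yojI", "mqo"])]
    (call,) = build_operon(shuffled, reference)
    assert call.match_status == "novel"
    assert call.matched_operon_id is None


def test_build_operon_minus_strand_transcription_order(reference):
    # on the minus strand the transcription order is descending start
    orfs = [orf_at(4000, "tauA", "-"), orf_at(1000, "tauB", "-")]
    (call,) = build_operon(orfs, reference)
    assert call.chain == "tauA-tauB"
    assert call.match_status == "exact"


def test_build_operon_mixed_strand_flag(reference):
    orfs = [orf_at(0, "tauA", "+"), orf_at(2000, "tauB", "-")]
    calls = build_operon(orfs, reference)
    assert len(calls) == 2
    assert all(c.mixed_strand for c in calls)


def test_build_operon_counts_unlabeled(reference):
    orfs = [orf_at(0, "tauA"), orf_at(1000, "tauB"), orf_at(2000, None)]
    (call,) = build_operon(orfs, reference)
    assert call.n_unlabeled == 1
    assert call.chain == "tauA-tauB"


def test_flag_duplicates_groups_by_identity(reference):
    def call_with_aa(cid, aa):
        orfs = [orf_at(0, "tauA", contig=cid), orf_at(1000, "tauB", contig=cid)]
        (c,) = build_operon(orfs, reference)
        c.aa_concat = aa
        return c

    base = "M" + "A" * 499
    variant = base[:250] + "V" + base[251:]  # 1 substitution in 500
    distant = "M" + "W" * 499
    calls = flag_duplicates(
        [call_with_aa("c1", base), call_with_aa("c2", variant), call_with_aa("c3", distant)]
    )
    groups = {c.contig_id: c.duplicate_group for c in calls}
    assert groups["c1"] == groups["c2"]
    assert groups["c3"] != groups["c1"]
    reps = [c.contig_id for c in calls if c.is_representative]
    assert len(reps) == 2


def test_planted_cassettes_recovered(scenario):
    for cid, planted in scenario.truth.planted_orfs.items():
        found = find_orfs(cid, scenario.contigs[cid], min_aa=100)
        coords = {(o.start, o.end, o.strand) for o in found}
        for orf in planted:
            assert (orf.start, orf.end, orf.strand) in coords
    assert scenario.truth.planted_chain
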