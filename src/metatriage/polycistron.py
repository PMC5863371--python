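"""Decoding polycistronic bacterial contigs.

A single assembled bacterial transcript can carry several ordered coding
regions (an operon). This module extracts open reading frames from all
six frames, optionally scores coding-likeness with a hexamer Markov
model, assembles the coordinate-ordered gene-symbol chain per contig and
matches it against a reference operon table, and groups near-identical
duplicate variants.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from Bio.Seq import Seq

from .core import NUCLEOTIDES, OperonReference

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfCall:
    """A predicted coding region; coordinates are 0-based half-open on
    the forward axis of the contig, stop codon included in the span."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_sequence: str
    partial5: bool = False
    partial3: bool = False
    gene_symbol: str | None = None
    coding_score: float | None = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        expected = (self.end - self.start) // 3 - (0 if self.partial3 else 1)
        if len(self.aa_sequence) != expected:
            raise ValueError(
                f"aa length {len(self.aa_sequence)} inconsistent with span "
                f"{self.start}-{self.end} (partial3={self.partial3})"
            )


@dataclass
class OperonCall:
    """Ordered gene chain of one polycistronic contig."""

    contig_id: str
    gene_symbols: tuple[str, ...]
    chain: str
    match_status: str  # exact | contiguous_subset | novel
    matched_operon_id: str | None = None
    strand: str = "+"
    mixed_strand: bool = False
    n_unlabeled: int = 0
    aa_concat: str = ""
    duplicate_group: int | None = None
    is_representative: bool = False


def _codon_is(codon: str, targets) -> bool:
    # codons containing N never match start or stop
    return "N" not in codon and codon in targets


def find_orfs(
    contig_id: str,
    sequence: str,
    min_aa: int = 100,
    require_start: bool = True,
    allow_edge_partials: bool = True,
) -> list[OrfCall]:
    """Six-frame ORF scan.

    Within each frame the codon string is segmented at stop codons; each
    segment yields at most one ORF, running from its first ATG (or from
    the contig edge for the frame's first segment when
    ``allow_edge_partials``, flagged ``partial5``) to the closing stop
    codon (included in the span) or to the contig edge (flagged
    ``partial3``). With ``require_start=False`` interior segments start
    directly after the previous stop. Minus-strand ORFs are reported on
    the forward axis. ORFs shorter than ``min_aa`` amino acids are
    dropped.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(sequence) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")
    length = len(sequence)
    out: list[OrfCall] = []
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else str(Seq(sequence).reverse_complement())
        for frame in range(3):
            n_codons = (len(seq) - frame) // 3
            if n_codons == 0:
                continue
            codons = [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(n_codons)]
            seg_start = 0
            i = 0
            while i <= n_codons:
                at_stop = i < n_codons and _codon_is(codons[i], STOP_CODONS)
                at_end = i == n_codons
                if not (at_stop or at_end):
                    i += 1
                    continue
                # segment = codons[seg_start:i], closed by stop at i or edge
                orf = _segment_orf(
                    contig_id,
                    codons,
                    seg_start,
                    i,
                    closed_by_stop=at_stop,
                    frame=frame,
                    strand=strand,
                    seq_len=len(seq),
                    contig_len=length,
                    min_aa=min_aa,
                    require_start=require_start,
                    allow_edge_partials=allow_edge_partials,
                )
                if orf is not None:
                    out.append(orf)
                seg_start = i + 1
                i += 1
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _segment_orf(
    contig_id,
    codons,
    seg_start,
    seg_end,
    closed_by_stop,
    frame,
    strand,
    seq_len,
    contig_len,
    min_aa,
    require_start,
    allow_edge_partials,
):
    if seg_end == seg_start and not closed_by_stop:
        return None
    first_segment = seg_start == 0
    partial5 = False
    if first_segment and allow_edge_partials:
        start_codon = seg_start
        partial5 = not (
            seg_end > seg_start and _codon_is(codons[seg_start], {START_CODON})
        )
    elif require_start:
        start_codon = None
        for c in range(seg_start, seg_end):
            if _codon_is(codons[c], {START_CODON}):
                start_codon = c
                break
        if start_codon is None:
            return None
    else:
        start_codon = seg_start
    if closed_by_stop:
        end_codon = seg_end + 1  # include the stop codon
        partial3 = False
        n_aa = seg_end - start_codon
    else:
        if not allow_edge_partials:
            return None
        end_codon = seg_end
        partial3 = True
        n_aa = seg_end - start_codon
    if n_aa < min_aa:
        return None
    # coordinates on the scanned strand
    s_local = frame + 3 * start_codon
    e_local = frame + 3 * end_codon
    if strand == "+":
        start, end = s_local, e_local
    else:
        start, end = contig_len - e_local, contig_len - s_local
    nt = "".join(codons[start_codon : start_codon + n_aa])
    aa = str(Seq(nt).translate())
    return OrfCall(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        aa_sequence=aa,
        partial5=partial5,
        partial3=partial3,
    )


# ---------------------------------------------------------------------------
# Hexamer coding score

class HexamerModel:
    """Log-likelihood-ratio coding score from hexamer frequencies.

    Trained on a coding sequence set; the background distribution comes
    from a nucleotide shuffle of the same set (seeded), so composition
    is preserved while codon structure is destroyed.
    """

    K = 6

    def __init__(self) -> None:
        self._log_ratio: dict[str, float] | None = None

    def train(self, coding_sequences: list[str], seed: int = 0) -> "HexamerModel":
        concat = "".join(s.upper() for s in coding_sequences)
        if len(concat) < 10_000:
            raise ValueError("need >= 10 kb of coding sequence to train")
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(concat)))
        coding = self._counts(concat)
        background = self._counts(shuffled)
        total_c = sum(coding.values())
        total_b = sum(background.values())
        self._log_ratio = {}
        from itertools import product

        for hexamer in map("".join, product("ACGT", repeat=self.K)):
            pc = (coding.get(hexamer, 0) + 1.0) / (total_c + 4**self.K)
            pb = (background.get(hexamer, 0) + 1.0) / (total_b + 4**self.K)
            self._log_ratio[hexamer] = float(np.log(pc / pb))
        return self

    def _counts(self, seq: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i in range(len(seq) - self.K + 1):
            h = seq[i : i + self.K]
            if set(h) <= set("ACGT"):
                counts[h] = counts.get(h, 0) + 1
        return counts

    def score(self, sequence: str) -> float:
        """Sum of log(P_coding/P_background) over sliding hexamers."""
        if self._log_ratio is None:
            raise ValueError("model not trained")
        sequence = sequence.upper()
        if len(sequence) < self.K:
            raise ValueError("sequence shorter than one hexamer")
        total = 0.0
        for i in range(len(sequence) - self.K + 1):
            h = sequence[i : i + self.K]
            total += self._log_ratio.get(h, 0.0)
        return total


# ---------------------------------------------------------------------------
# Operon chains

def build_operon(
    orf_calls: list[OrfCall],
    reference: OperonReference,
    mixed_strand_ratio: float = 0.5,
) -> list[OperonCall]:
    """Assemble the gene chain(s) of one contig and match against the
    reference.

    Labeled ORFs are ordered along the direction of transcription of
    their strand (ascending start on +, descending on -). When the
    minority strand carries at least ``mixed_strand_ratio`` times as
    many labeled ORFs as the majority strand, one chain per strand is
    produced and both are flagged mixed-strand; otherwise only the
    majority strand forms a chain. Match status is ``exact`` when the
    chain equals a reference row, ``contiguous_subset`` when it is a
    contiguous sub-chain of one, else ``novel``.
    """
    if not orf_calls:
        raise ValueError("no ORF calls supplied")
    contig_ids = {o.contig_id for o in orf_calls}
    if len(contig_ids) > 1:
        raise ValueError(f"ORFs span multiple contigs: {sorted(contig_ids)}")
    contig_id = contig_ids.pop()
    labeled = [o for o in orf_calls if o.gene_symbol]
    n_unlabeled = len(orf_calls) - len(labeled)
    by_strand = {"+": [o for o in labeled if o.strand == "+"],
                 "-": [o for o in labeled if o.strand == "-"]}
    n_plus, n_minus = len(by_strand["+"]), len(by_strand["-"])
    if n_plus == 0 and n_minus == 0:
        return [
            OperonCall(
                contig_id=contig_id,
                gene_symbols=(),
                chain="",
                match_status="novel",
                n_unlabeled=n_unlabeled,
            )
        ]
    major = "+" if n_plus >= n_minus else "-"
    minor = "-" if major == "+" else "+"
    strands = [major]
    mixed = (
        len(by_strand[minor]) > 0
        and len(by_strand[minor]) >= mixed_strand_ratio * len(by_strand[major])
    )
    if mixed:
        strands.append(minor)
    calls = []
    for strand in strands:
        orfs = sorted(
            by_strand[strand],
            key=lambda o: o.start,
            reverse=(strand == "-"),
        )
        if not orfs:
            continue
        symbols = tuple(o.gene_symbol for o in orfs)
        status, matched = match_chain(symbols, reference)
        calls.append(
            OperonCall(
                contig_id=contig_id,
                gene_symbols=symbols,
                chain="-".join(symbols),
                match_status=status,
                matched_operon_id=matched,
                strand=strand,
                mixed_strand=mixed,
                n_unlabeled=n_unlabeled,
                aa_concat="".join(o.aa_sequence for o in orfs),
            )
        )
    return calls


def match_chain(
    symbols: tuple[str, ...], reference: OperonReference
) -> tuple[str, str | None]:
    for oid, genes in reference.items():
        if symbols == genes:
            return "exact", oid
    for oid, genes in reference.items():
        if len(symbols) < len(genes):
            for off in range(len(genes) - len(symbols) + 1):
                if genes[off : off + len(symbols)] == symbols:
                    return "contiguous_subset", oid
    return "novel", None


def _identity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def flag_duplicates(
    operon_calls: list[OperonCall], identity_threshold: float = 0.98
) -> list[OperonCall]:
    """Group near-identical operon variants.

    Calls with identical chains whose concatenated amino-acid sequences
    reach the global identity threshold fall in one group (transitive
    closure); the longest member of each group is its representative.
    Returns new calls with ``duplicate_group``/``is_representative`` set.
    """
    if not operon_calls:
        raise ValueError("no operon calls supplied")
    n = len(operon_calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = operon_calls[i], operon_calls[j]
            if a.chain != b.chain or not a.chain:
                continue
            if _identity(a.aa_concat, b.aa_concat) >= identity_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = list(operon_calls)
    for gid, members in enumerate(sorted(groups.values(), key=min)):
        rep = max(members, key=lambda i: len(operon_calls[i].aa_concat))
        for i in members:
            out[i] = replace(
                operon_calls[i], duplicate_group=gid, is_representative=(i == rep)
            )
    return out
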