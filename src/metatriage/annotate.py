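"""Unconstrained annotation triage.

Every contig is annotated without any prior assumption about which
organism it comes from: hits from a tiered cascade of databases are
ranked by percent of maximum potential bitscore (PMPB) — the hit's
bitscore as a percentage of the query's self-alignment bitscore — the
best hit becomes the primary annotation, and all hits within a window
(default 10 percentage points) of the primary are retained as secondary
annotations. Primaries with uninformative descriptions ("hypothetical",
"predicted", ...) are demoted in favour of an equally good informative
secondary when one exists. Resolved taxa are rolled up into a
Krona-style taxonomy tree carrying contig counts and summed abundance.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from Bio.Align import substitution_matrices

from .core import HitRecord, Lineage, SelfScoreTable, TaxonomyTable

DEFAULT_STOPLIST = frozenset(
    {
        "hypothetical",
        "predicted",
        "putative",
        "uncharacterized",
        "uncharacterised",
        "unknown",
    }
)


@dataclass(frozen=True)
class ScoringScheme:
    """Ungapped Karlin-Altschul parameters plus per-residue self scores.

    ``diagonal`` maps each residue to its substitution-matrix self score
    (protein) or match reward (nucleotide); ``lam`` and ``k`` are the
    ungapped Karlin-Altschul constants of the scheme, used to convert a
    raw self-alignment score to bits.
    """

    name: str
    diagonal: dict[str, int]
    lam: float
    k: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")
        if any(v <= 0 for v in self.diagonal.values()):
            raise ValueError("diagonal scores must be positive")

    @classmethod
    def blosum62_ungapped(cls) -> "ScoringScheme":
        """BLOSUM62 with the published ungapped constants
        (lambda = 0.3176, K = 0.134)."""
        mat = substitution_matrices.load("BLOSUM62")
        # standard residues only: the ambiguity codes B/Z/X carry
        # non-positive self scores and have no defined "maximum potential"
        standard = "ARNDCQEGHILKMFPSTWYV"
        diag = {aa: int(mat[aa, aa]) for aa in standard}
        return cls("blosum62_ungapped", diag, lam=0.3176, k=0.134)

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        """blastn defaults: match +1, ungapped lambda = 1.28, K = 0.46."""
        diag = {b: 1 for b in "ACGT"}
        return cls("blastn_ungapped", diag, lam=1.28, k=0.46)


@dataclass(frozen=True)
class Tier:
    """One level of the database cascade."""

    tier_id: int
    evalue_cutoff: float
    molecule: str = "protein"  # protein | nucleotide
    applies_to: str = "all"  # all | de_only | no_hit_only

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue cutoff must be positive")
        if self.molecule not in ("protein", "nucleotide"):
            raise ValueError(f"unknown molecule {self.molecule!r}")
        if self.applies_to not in ("all", "de_only", "no_hit_only"):
            raise ValueError(f"unknown applies_to {self.applies_to!r}")


@dataclass
class TierConfig:
    """Ordered cascade tiers, the secondary-annotation window (percentage
    points of PMPB) and the uninformative-description stoplist."""

    tiers: tuple[Tier, ...] = ()
    secondary_window: float = 10.0
    stoplist: frozenset[str] = DEFAULT_STOPLIST

    def __post_init__(self) -> None:
        if self.secondary_window < 0:
            raise ValueError("secondary window must be >= 0")
        if not self.tiers:
            self.tiers = default_tiers()


def default_tiers() -> tuple[Tier, ...]:
    """The canonical cascade: a primary protein tier for all contigs
    (e-value < 1e-4), a fallback protein tier for DE contigs with no hit
    so far (1e-4), and a nucleotide tier for DE contigs (1e-6)."""
    return (
        Tier(1, 1e-4, "protein", "all"),
        Tier(2, 1e-4, "protein", "de_only"),
        Tier(3, 1e-6, "nucleotide", "de_only"),
    )


@dataclass
class AnnotationCall:
    """Triage outcome for one contig."""

    contig_id: str
    status: str  # annotated | unknown
    tier: int | None = None
    primary: HitRecord | None = None
    primary_pmpb: float | None = None
    secondary: list[tuple[HitRecord, float]] = field(default_factory=list)
    resolved_description: str = ""
    resolved_lineage: Lineage | None = None
    demoted: bool = False  # primary replaced by an informative secondary


# ---------------------------------------------------------------------------
# PMPB

def compute_max_bitscore(sequence: str, scheme: ScoringScheme) -> float:
    """Self-alignment bitscore: raw score = sum of diagonal scores over
    the sequence, converted with bits = (lambda*S - ln K) / ln 2."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        raw = sum(scheme.diagonal[res] for res in sequence.upper())
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not covered by scheme {scheme.name}")
    return (scheme.lam * raw - math.log(scheme.k)) / math.log(2.0)


def pmpb(hit_bitscore: float, max_bitscore: float) -> float:
    """Percent of maximum potential bitscore, capped at 100.

    Third-party bitscore rounding can push a hit marginally above a
    computed self-score; such values are capped with a warning rather
    than rejected.
    """
    if max_bitscore <= 0:
        raise ValueError("max bitscore must be positive")
    value = 100.0 * hit_bitscore / max_bitscore
    if value > 100.0:
        warnings.warn(
            f"hit bitscore {hit_bitscore} exceeds self-score {max_bitscore}; "
            "PMPB capped at 100",
            stacklevel=2,
        )
        return 100.0
    return value


def _tie_key(hit_pmpb: float, hit: HitRecord):
    # higher PMPB wins; ties broken by lower e-value, lower tier, subject id
    return (-hit_pmpb, hit.evalue, hit.db_tier, hit.subject_id)


def select_annotation(
    hits: list[HitRecord],
    self_score: float,
    tier: Tier,
    window: float = 10.0,
) -> tuple[tuple[HitRecord, float], list[tuple[HitRecord, float]]] | None:
    """Select the primary annotation and within-window secondaries for
    one contig's hits in one tier.

    Hits at or above the tier's e-value cutoff are discarded. The
    primary is the maximum-PMPB hit (ties: lower e-value, then lower
    tier, then lexicographic subject id); secondaries are all other hits
    with PMPB >= primary - window, deduplicated by subject id (best kept).
    Returns ``None`` when no hit survives the cutoff.
    """
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    if self_score is None or self_score <= 0:
        raise ValueError(f"missing self-score for query {hits[0].query_id}")
    surviving = [h for h in hits if h.evalue < tier.evalue_cutoff]
    if not surviving:
        return None
    scored = [(h, pmpb(h.bitscore, self_score)) for h in surviving]
    scored.sort(key=lambda hp: _tie_key(hp[1], hp[0]))
    primary, primary_pmpb = scored[0]
    best_by_subject: dict[str, tuple[HitRecord, float]] = {}
    for h, p in scored[1:]:
        if p < primary_pmpb - window:
            continue
        if h.subject_id == primary.subject_id:
            continue
        if h.subject_id not in best_by_subject:
            best_by_subject[h.subject_id] = (h, p)
    secondary = sorted(best_by_subject.values(), key=lambda hp: _tie_key(hp[1], hp[0]))
    return (primary, primary_pmpb), secondary


def cascade_annotate(
    contig_ids: list[str],
    hits_by_tier: dict[int, list[HitRecord]],
    self_scores: SelfScoreTable,
    config: TierConfig,
    de_flags: dict[str, bool] | None = None,
) -> dict[str, AnnotationCall]:
    """Run the tier cascade for every contig.

    Each contig resolves at the first applicable tier that yields a hit
    (earlier tiers take precedence even if a later tier scores higher);
    contigs with no hit at any applicable tier are ``unknown``.
    """
    de_flags = de_flags or {}
    if any(t.applies_to == "de_only" for t in config.tiers) and not de_flags:
        warnings.warn("de_only tiers configured but no DE flags supplied", stacklevel=2)
    grouped: dict[int, dict[str, list[HitRecord]]] = {}
    for tier_id, hits in hits_by_tier.items():
        byq: dict[str, list[HitRecord]] = {}
        for h in hits:
            byq.setdefault(h.query_id, []).append(h)
        grouped[tier_id] = byq

    calls: dict[str, AnnotationCall] = {}
    for cid in contig_ids:
        call = AnnotationCall(contig_id=cid, status="unknown")
        for tier in config.tiers:
            if tier.applies_to == "de_only" and not de_flags.get(cid, False):
                continue
            # no_hit_only and the cascade itself both mean "not yet resolved"
            contig_hits = grouped.get(tier.tier_id, {}).get(cid)
            if not contig_hits:
                continue
            score = self_scores.get(cid)
            if score is None:
                raise ValueError(f"missing self-score for contig {cid}")
            selection = select_annotation(contig_hits, score, tier, config.secondary_window)
            if selection is None:
                continue
            (primary, primary_pmpb), secondary = selection
            call = AnnotationCall(
                contig_id=cid,
                status="annotated",
                tier=tier.tier_id,
                primary=primary,
                primary_pmpb=primary_pmpb,
                secondary=secondary,
                resolved_description=primary.subject_description,
            )
            break
        calls[cid] = resolve_description(call, config.stoplist) if call.status == "annotated" else call
    return calls


def is_uninformative(description: str, stoplist=DEFAULT_STOPLIST) -> bool:
    low = description.lower()
    return (not low.strip()) or any(term in low for term in stoplist)


def resolve_description(call: AnnotationCall, stoplist=DEFAULT_STOPLIST) -> AnnotationCall:
    """Demote an uninformative primary in favour of the best informative
    secondary within the window, if one exists.

    Promotion swaps the hits (the old primary becomes a secondary) and
    changes the taxon of record along with the description; the call is
    flagged ``demoted`` so downstream reports can surface the swap.
    """
    if call.status != "annotated":
        return call
    if not is_uninformative(call.primary.subject_description, stoplist):
        call.resolved_description = call.primary.subject_description
        return call
    eligible = [
        (h, p)
        for h, p in call.secondary
        if not is_uninformative(h.subject_description, stoplist)
    ]
    if not eligible:
        call.resolved_description = call.primary.subject_description
        return call
    eligible.sort(key=lambda hp: _tie_key(hp[1], hp[0]))
    new_primary, new_pmpb = eligible[0]
    demoted = [(call.primary, call.primary_pmpb)]
    demoted += [(h, p) for h, p in call.secondary if h.subject_id != new_primary.subject_id]
    demoted.sort(key=lambda hp: _tie_key(hp[1], hp[0]))
    return replace(
        call,
        primary=new_primary,
        primary_pmpb=new_pmpb,
        secondary=demoted,
        resolved_description=new_primary.subject_description,
        demoted=True,
    )


# ---------------------------------------------------------------------------
# Taxonomy rollup

@dataclass
class TaxonNode:
    """Node of the taxonomy tree; counts and tpm include all descendants."""

    name: str
    rank: str | None = None
    n_contigs: int = 0
    total_tpm: float = 0.0
    children: dict[str, "TaxonNode"] = field(default_factory=dict)

    def child(self, name: str, rank: str | None) -> "TaxonNode":
        if name not in self.children:
            self.children[name] = TaxonNode(name=name, rank=rank)
        return self.children[name]

    def walk(self, path=()):
        yield path, self
        for name, node in self.children.items():
            yield from node.walk(path + (name,))


UNKNOWN_NODE = "Unknown"
UNCLASSIFIED_NODE = "unclassified"


def resolve_lineage(call: AnnotationCall, taxonomy: TaxonomyTable) -> AnnotationCall:
    """Attach the taxonomy lineage of the primary hit's taxon key; keys
    missing from the table resolve to a one-level 'unclassified' lineage."""
    if call.status != "annotated":
        return call
    lineage = taxonomy.get(call.primary.subject_taxon)
    if lineage is None:
        lineage = Lineage((("superkingdom", UNCLASSIFIED_NODE),))
    call.resolved_lineage = lineage
    return call


def taxonomic_rollup(
    calls: dict[str, AnnotationCall],
    taxonomy: TaxonomyTable,
    mean_tpm: dict[str, float] | None = None,
) -> TaxonNode:
    """Build the Krona-style tree: per node, the number of contigs and
    the summed mean tpm of everything at or below it. Unknown-status
    contigs land under a reserved top-level 'Unknown' node."""
    mean_tpm = mean_tpm or {}
    root = TaxonNode(name="root")
    for cid, call in calls.items():
        tpm = float(mean_tpm.get(cid, 0.0))
        root.n_contigs += 1
        root.total_tpm += tpm
        if call.status != "annotated":
            node = root.child(UNKNOWN_NODE, None)
            node.n_contigs += 1
            node.total_tpm += tpm
            continue
        call = resolve_lineage(call, taxonomy)
        node = root
        for rank, name in call.resolved_lineage.pairs:
            node = node.child(name, rank)
            node.n_contigs += 1
            node.total_tpm += tpm
    return root
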