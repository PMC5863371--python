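"""Seeded multi-kingdom metatranscriptome scenario with ground truth.

The generator emulates the community structure of a contaminated-soil
root metatranscriptome: a stable plant clade, a fungal clade mostly down
in treatment, a second fungal clade mostly treatment-exclusive, and a
bacterial family uniformly up in treatment, with roughly a third of
contigs carrying no protein homology ("unknown"), negative-binomial
count noise over 6+6 replicates, decoy hits inside and outside the
secondary-annotation window, and polycistronic bacterial contigs with
planted, reference-ordered gene cassettes.

Homology is simulated at the hit-table level (PMPB structure is planted
directly, self-scores are emitted alongside), not through sequence
similarity; sequences are random nucleotides except the planted ORF
cassettes. Everything is a deterministic function of the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as mio
from .core import (
    CONTROL,
    TREATMENT,
    ContigSet,
    CountMatrix,
    HitRecord,
    Lineage,
    OperonReference,
    SelfScoreTable,
    TaxonomyTable,
)

EE = "EE"
DE_UP = "DE_up"
DE_DOWN = "DE_down"
EXCL_T = "exclusive_treatment"
EXCL_C = "exclusive_control"

_PROFILE_STATE = {
    "stable": EE,
    "down_in_treatment": DE_DOWN,
    "up_in_treatment": DE_UP,
    "exclusive_treatment": EXCL_T,
    "exclusive_control": EXCL_C,
    "uniform_up_bacterial": DE_UP,
}

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class CladeSpec:
    name: str
    taxon_key: str
    lineage: str  # "rank:name;rank:name;..."
    n_contigs: int
    profile: str
    base_mean: float = 60.0
    dispersion: float = 0.1
    fold_change: float = 4.0
    polycistronic: bool = False

    def __post_init__(self) -> None:
        if self.profile not in _PROFILE_STATE:
            raise ValueError(f"unknown expression profile {self.profile!r}")
        if self.n_contigs < 0 or self.base_mean < 0:
            raise ValueError("counts and means must be >= 0")


@dataclass(frozen=True)
class DecoySpec:
    """Decoy hits planted around the intended primary annotation."""

    n_in_window: int = 2
    n_out_of_window: int = 2
    fraction_with_decoys: float = 0.5
    in_window_gap: tuple[float, float] = (0.5, 9.5)  # PMPB points below primary
    out_window_gap: tuple[float, float] = (11.0, 30.0)


@dataclass(frozen=True)
class PolycistronSpec:
    n_contigs: int = 8
    gene_aa_range: tuple[int, int] = (100, 140)
    spacer_range: tuple[int, int] = (9, 30)
    min_orf_aa: int = 100


def default_clades() -> tuple[CladeSpec, ...]:
    euk = "superkingdom:Eukaryota;kingdom:"
    return (
        CladeSpec(
            "salix_like",
            "tax_salix",
            euk + "Viridiplantae;phylum:Streptophyta;family:Salicaceae;"
            "genus:Salix;species:Salix purpurea",
            800,
            "stable",
            base_mean=80.0,
        ),
        CladeSpec(
            "asco_like",
            "tax_asco",
            euk + "Fungi;phylum:Ascomycota;family:Nectriaceae;"
            "genus:Fusarium;species:Fusarium sp",
            500,
            "down_in_treatment",
            base_mean=80.0,
        ),
        CladeSpec(
            "asco_ctrl_only",
            "tax_asco2",
            euk + "Fungi;phylum:Ascomycota;family:Nectriaceae;"
            "genus:Fusarium;species:Fusarium solani",
            15,
            "exclusive_control",
            base_mean=60.0,
        ),
        CladeSpec(
            "basidio_excl",
            "tax_basidio",
            euk + "Fungi;phylum:Basidiomycota;family:Serendipitaceae;"
            "genus:Serendipita;species:Serendipita vermifera",
            300,
            "exclusive_treatment",
            base_mean=60.0,
        ),
        CladeSpec(
            "basidio_up",
            "tax_basidio2",
            euk + "Fungi;phylum:Basidiomycota;family:Serendipitaceae;"
            "genus:Serendipita;species:Serendipita indica",
            150,
            "up_in_treatment",
            base_mean=60.0,
        ),
        CladeSpec(
            "entero",
            "tax_entero",
            "superkingdom:Bacteria;kingdom:Bacteria;phylum:Proteobacteria;"
            "class:Gammaproteobacteria;family:Enterobacteriaceae;"
            "genus:Escherichia;species:Escherichia coli",
            250,
            "uniform_up_bacterial",
            base_mean=100.0,
        ),
        CladeSpec(
            "entero_poly",
            "tax_entero",
            "superkingdom:Bacteria;kingdom:Bacteria;phylum:Proteobacteria;"
            "class:Gammaproteobacteria;family:Enterobacteriaceae;"
            "genus:Escherichia;species:Escherichia coli",
            8,
            "uniform_up_bacterial",
            base_mean=100.0,
            polycistronic=True,
        ),
    )


def default_operon_reference() -> OperonReference:
    return OperonReference(
        {
            "opr_alk": ("yojI", "alkB", "ada", "apbE", "mqo"),
            "opr_ssu": ("ssuA", "ssuB", "ssuC", "ssuD", "ssuE"),
            "opr_tauAB": ("tauA", "tauB"),
            "opr_tauCD": ("tauC", "tauD"),
            "opr_mla": ("mlaC", "mlaD", "mlaE", "mlaF"),
            "opr_rml": ("rmlA", "rmlB", "rmlC", "rmlD"),
        }
    )


@dataclass
class ScenarioConfig:
    seed: int = 0
    n_replicates_per_condition: int = 6
    clades: tuple[CladeSpec, ...] = field(default_factory=default_clades)
    fraction_unknown: float = 0.34
    decoys: DecoySpec = field(default_factory=DecoySpec)
    polycistron: PolycistronSpec = field(default_factory=PolycistronSpec)
    mean_lognorm_sigma: float = 0.5  # contig-to-contig spread of true means
    size_factor_sigma: float = 0.1  # spread of true per-sample depth factors
    fraction_tier2: float = 0.05  # DE contigs resolved only at the fallback tier
    contig_length_range: tuple[int, int] = (300, 1500)

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_unknown <= 1:
            raise ValueError("fraction_unknown must lie in [0, 1]")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if not self.clades or sum(c.n_contigs for c in self.clades) == 0:
            raise ValueError("degenerate config: no contigs to generate")


@dataclass(frozen=True)
class PlantedOrf:
    start: int
    end: int  # 0-based half-open, stop codon included
    strand: str
    gene_symbol: str
    order: int


@dataclass
class ContigTruth:
    clade: str
    taxon_key: str
    de_state: str
    true_fc: float
    is_unknown: bool
    intended_tier: int | None
    intended_primary: str | None
    intended_secondary: tuple[str, ...] = ()


@dataclass
class GroundTruth:
    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    planted_orfs: dict[str, tuple[PlantedOrf, ...]] = field(default_factory=dict)
    planted_chain: dict[str, str] = field(default_factory=dict)
    planted_operon_id: dict[str, str] = field(default_factory=dict)
    planted_match_status: dict[str, str] = field(default_factory=dict)


@dataclass
class Scenario:
    contigs: ContigSet
    counts: CountMatrix
    lengths: dict[str, float]
    hits_by_tier: dict[int, list[HitRecord]]
    self_scores: SelfScoreTable
    taxonomy: TaxonomyTable
    operon_reference: OperonReference
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        """Persist every piece in the formats the readers consume; the
        ground truth goes to a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": outdir / "contigs.fasta",
            "counts": outdir / "counts.tsv",
            "lengths": outdir / "lengths.tsv",
            "self_scores": outdir / "self_scores.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "operons": outdir / "operons.tsv",
        }
        mio.write_fasta(self.contigs, paths["contigs"])
        mio.write_counts(self.counts, paths["counts"])
        mio.write_lengths(self.lengths, paths["lengths"])
        mio.write_self_scores(self.self_scores, paths["self_scores"])
        mio.write_taxonomy(self.taxonomy, paths["taxonomy"])
        mio.write_operon_reference(self.operon_reference, paths["operons"])
        for tier, hits in sorted(self.hits_by_tier.items()):
            p = outdir / f"hits_tier{tier}.tsv"
            mio.write_hits(hits, p)
            paths[f"hits_tier{tier}"] = p
        truth = {
            "contigs": {
                cid: {
                    "clade": t.clade,
                    "taxon_key": t.taxon_key,
                    "de_state": t.de_state,
                    "true_fc": t.true_fc,
                    "is_unknown": t.is_unknown,
                    "intended_tier": t.intended_tier,
                    "intended_primary": t.intended_primary,
                    "intended_secondary": list(t.intended_secondary),
                }
                for cid, t in self.truth.contigs.items()
            },
            "planted_orfs": {
                cid: [
                    {
                        "start": o.start,
                        "end": o.end,
                        "strand": o.strand,
                        "gene_symbol": o.gene_symbol,
                        "order": o.order,
                    }
                    for o in orfs
                ]
                for cid, orfs in self.truth.planted_orfs.items()
            },
            "planted_chain": self.truth.planted_chain,
            "planted_operon_id": self.truth.planted_operon_id,
            "planted_match_status": self.truth.planted_match_status,
        }
        mio.write_report(truth, outdir / "ground_truth.json", format="json")
        paths["ground_truth"] = outdir / "ground_truth.json"
        return {k: str(v) for k, v in paths.items()}




def _floor1(x: float) -> float:
    """Round a bitscore down to one decimal so serialisation can never
    push it above the (separately truncated) self-score."""
    import math
    return max(math.floor(x * 10.0) / 10.0, 0.1)

def orf_query_id(contig_id: str, start: int, end: int, strand: str) -> str:
    """Key under which ORF-level homology hits and self-scores are filed."""
    return f"{contig_id}|{start}-{end}|{strand}"


# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)


def _gene_cassette(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) random sense codons + TAA; no internal stop or
    in-frame ATG, so the planted start is unambiguous."""
    body = "".join(rng.choice(_SENSE_CODONS, size=n_aa - 1))
    return "ATG" + body + "TAA"


def _polycistronic_contig(
    rng: np.random.Generator,
    contig_id: str,
    genes: tuple[str, ...],
    spec: PolycistronSpec,
    minus_strand: bool,
) -> tuple[str, tuple[PlantedOrf, ...]]:
    """Concatenate spacer+cassette blocks; each spacer ends with TAA so
    the codon preceding every planted ATG (in the gene's frame) is a
    stop, making the recovered start coordinate exact."""
    parts: list[str] = []
    orfs: list[PlantedOrf] = []
    pos = 0
    for order, symbol in enumerate(genes):
        spacer = _random_seq(rng, int(rng.integers(*spec.spacer_range))) + "TAA"
        parts.append(spacer)
        pos += len(spacer)
        n_aa = int(rng.integers(spec.gene_aa_range[0], spec.gene_aa_range[1] + 1))
        cassette = _gene_cassette(rng, n_aa)
        orfs.append(PlantedOrf(pos, pos + len(cassette), "+", symbol, order))
        parts.append(cassette)
        pos += len(cassette)
    parts.append(_random_seq(rng, int(rng.integers(*spec.spacer_range))))
    seq = "".join(parts)
    if minus_strand:
        length = len(seq)
        seq = str(Seq(seq).reverse_complement())
        orfs = [
            PlantedOrf(length - o.end, length - o.start, "-", o.gene_symbol, o.order)
            for o in orfs
        ]
    return seq, tuple(orfs)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full scenario; identical config (incl. seed) gives
    byte-identical outputs."""
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_replicates_per_condition
    samples = [f"ctrl_{i+1}" for i in range(n_rep)] + [
        f"trt_{i+1}" for i in range(n_rep)
    ]
    conditions = {
        s: (CONTROL if s.startswith("ctrl") else TREATMENT) for s in samples
    }
    true_s = np.exp(rng.normal(0.0, config.size_factor_sigma, size=2 * n_rep))

    taxonomy: TaxonomyTable = {}
    operon_ref = default_operon_reference()
    truth = GroundTruth()
    sequences: dict[str, str] = {}
    lengths: dict[str, float] = {}
    count_rows: dict[str, np.ndarray] = {}
    self_scores: SelfScoreTable = {}
    hits_by_tier: dict[int, list[HitRecord]] = {1: [], 2: [], 3: []}

    # taxonomy: clade taxa plus a sibling "alt" taxon per clade for decoys
    for clade in config.clades:
        lineage = Lineage.parse(clade.lineage)
        taxonomy.setdefault(clade.taxon_key, lineage)
        alt_pairs = tuple(
            (r, (n + " (sibling)") if r == "species" else n) for r, n in lineage.pairs
        )
        taxonomy.setdefault(clade.taxon_key + "_alt", Lineage(alt_pairs))

    # ---- counts, sequences, contig bookkeeping -----------------------------
    contig_meta: list[tuple[str, CladeSpec]] = []
    operon_rows = list(default_operon_reference().items())
    poly_counter = 0
    for clade in config.clades:
        for k in range(clade.n_contigs):
            cid = f"{clade.name}_c{k+1:04d}"
            contig_meta.append((cid, clade))
            state = _PROFILE_STATE[clade.profile]
            fc = {
                EE: 1.0,
                DE_UP: clade.fold_change,
                DE_DOWN: 1.0 / clade.fold_change,
                EXCL_T: float("inf"),
                EXCL_C: 0.0,
            }[state]
            m_g = clade.base_mean * float(
                np.exp(rng.normal(0.0, config.mean_lognorm_sigma))
            )
            eff_c = 0.0 if state == EXCL_T else 1.0
            eff_t = 0.0 if state == EXCL_C else (fc if np.isfinite(fc) and fc > 0 else 1.0)
            mu = np.concatenate(
                [
                    m_g * eff_c * true_s[:n_rep],
                    m_g * eff_t * true_s[n_rep:],
                ]
            )
            phi = clade.dispersion
            row = np.zeros(2 * n_rep, dtype=int)
            pos = mu > 0
            if phi > 0:
                size = 1.0 / phi
                p = size / (size + mu[pos])
                row[pos] = rng.negative_binomial(size, p)
            else:
                row[pos] = rng.poisson(mu[pos])
            # exclusive contigs must be present in their own condition
            if state in (EXCL_T, EXCL_C) and row.sum() == 0:
                row[np.argmax(mu)] = max(1, int(round(m_g)))
            count_rows[cid] = row

            if clade.polycistronic:
                operon_id, genes = operon_rows[poly_counter % len(operon_rows)]
                status = "exact"
                if poly_counter >= len(operon_rows) and len(genes) > 2:
                    # wrap-around contigs carry a truncated chain so the
                    # contiguous-subset match path is exercised too
                    genes = genes[: len(genes) - 1]
                    status = "contiguous_subset"
                minus = poly_counter % 4 == 3
                seq, orfs = _polycistronic_contig(
                    rng, cid, genes, config.polycistron, minus
                )
                sequences[cid] = seq
                truth.planted_orfs[cid] = orfs
                ordered = sorted(orfs, key=lambda o: o.order)
                truth.planted_chain[cid] = "-".join(o.gene_symbol for o in ordered)
                truth.planted_operon_id[cid] = operon_id
                truth.planted_match_status[cid] = status
                poly_counter += 1
            else:
                sequences[cid] = _random_seq(
                    rng, int(rng.integers(*config.contig_length_range))
                )
            lengths[cid] = float(len(sequences[cid]))
            truth.contigs[cid] = ContigTruth(
                clade=clade.name,
                taxon_key=clade.taxon_key,
                de_state=state,
                true_fc=fc,
                is_unknown=False,
                intended_tier=None,
                intended_primary=None,
            )

    # ---- choose the unknown fraction --------------------------------------
    all_ids = [cid for cid, _ in contig_meta]
    n_unknown = int(round(config.fraction_unknown * len(all_ids)))
    # polycistronic contigs always stay annotated (they anchor the operon path)
    eligible = np.array(
        [cid for cid, clade in contig_meta if not clade.polycistronic]
    )
    unknown_ids = set(rng.choice(eligible, size=min(n_unknown, len(eligible)), replace=False))

    # ---- hit tables, self-scores -------------------------------------------
    de_states = {EXCL_T, EXCL_C, DE_UP, DE_DOWN}
    for cid, clade in contig_meta:
        self_scores[cid] = float(rng.uniform(150.0, 400.0))
        t = truth.contigs[cid]
        if cid in unknown_ids:
            t.is_unknown = True
            continue
        tier = 1
        if (
            not clade.polycistronic
            and t.de_state in de_states
            and rng.random() < config.fraction_tier2
        ):
            tier = 2
        t.intended_tier = tier
        primary_pmpb = float(rng.uniform(60.0, 100.0))
        primary_id = f"sbj_{cid}_primary"
        t.intended_primary = primary_id
        hits_by_tier[tier].append(
            HitRecord(
                query_id=cid,
                subject_id=primary_id,
                percent_identity=float(np.round(rng.uniform(40, 99), 1)),
                align_len=int(rng.integers(80, 400)),
                evalue=float(10.0 ** rng.uniform(-60, -20)),
                bitscore=_floor1(primary_pmpb / 100.0 * self_scores[cid]),
                subject_description=f"{clade.name} marker protein {cid}",
                subject_taxon=clade.taxon_key,
                db_tier=tier,
            )
        )
        if rng.random() < config.decoys.fraction_with_decoys:
            secondaries = []
            for d in range(config.decoys.n_in_window):
                gap = float(rng.uniform(*config.decoys.in_window_gap))
                sid = f"sbj_{cid}_inwin{d+1}"
                secondaries.append(sid)
                desc = (
                    f"hypothetical protein {cid}_{d}"
                    if rng.random() < 0.3
                    else f"{clade.name} related protein {cid}_{d}"
                )
                hits_by_tier[tier].append(
                    HitRecord(
                        query_id=cid,
                        subject_id=sid,
                        percent_identity=float(np.round(rng.uniform(35, 95), 1)),
                        align_len=int(rng.integers(80, 400)),
                        evalue=float(10.0 ** rng.uniform(-40, -10)),
                        bitscore=_floor1(max(primary_pmpb - gap, 1.0) / 100.0 * self_scores[cid]),
                        subject_description=desc,
                        subject_taxon=clade.taxon_key + "_alt",
                        db_tier=tier,
                    )
                )
            for d in range(config.decoys.n_out_of_window):
                gap = float(rng.uniform(*config.decoys.out_window_gap))
                hits_by_tier[tier].append(
                    HitRecord(
                        query_id=cid,
                        subject_id=f"sbj_{cid}_outwin{d+1}",
                        percent_identity=float(np.round(rng.uniform(25, 80), 1)),
                        align_len=int(rng.integers(60, 300)),
                        evalue=float(10.0 ** rng.uniform(-20, -5)),
                        bitscore=_floor1(max(primary_pmpb - gap, 0.5) / 100.0 * self_scores[cid]),
                        subject_description=f"distant homologue {cid}_{d}",
                        subject_taxon=clade.taxon_key + "_alt",
                        db_tier=tier,
                    )
                )
            t.intended_secondary = tuple(secondaries)

    # ---- ORF-level hits for polycistronic contigs --------------------------
    for cid, orfs in truth.planted_orfs.items():
        for orf in orfs:
            qid = orf_query_id(cid, orf.start, orf.end, orf.strand)
            self_scores[qid] = float(rng.uniform(150.0, 400.0))
            p = float(rng.uniform(80.0, 100.0))
            hits_by_tier[1].append(
                HitRecord(
                    query_id=qid,
                    subject_id=f"ref_{orf.gene_symbol}",
                    percent_identity=float(np.round(rng.uniform(60, 99), 1)),
                    align_len=(orf.end - orf.start) // 3,
                    evalue=float(10.0 ** rng.uniform(-80, -30)),
                    bitscore=_floor1(p / 100.0 * self_scores[qid]),
                    subject_description=orf.gene_symbol,
                    subject_taxon="tax_entero",
                    db_tier=1,
                )
            )

    counts = CountMatrix(
        pd.DataFrame.from_dict(count_rows, orient="index", columns=samples),
        conditions,
    )
    return Scenario(
        contigs=ContigSet(sequences),
        counts=counts,
        lengths=lengths,
        hits_by_tier=hits_by_tier,
        self_scores=self_scores,
        taxonomy=taxonomy,
        operon_reference=operon_ref,
        truth=truth,
    )


def null_scenario(config: ScenarioConfig) -> Scenario:
    """Same generation with every expression effect removed: all clades
    become 'stable', so every contig is truly EE."""
    clades = tuple(replace(c, profile="stable") for c in config.clades)
    return generate_scenario(replace(config, clades=clades))


def flat_config(
    seed: int,
    n_contigs: int = 2000,
    frac_de: float = 0.0,
    fold: float = 4.0,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    n_replicates: int = 6,
    mean_sigma: float = 0.5,
) -> ScenarioConfig:
    """Single-kingdom calibration config: ``frac_de`` of contigs at a
    true ``fold`` change (split evenly up/down), the rest EE. Used for
    the null and power studies of the DE model."""
    n_de = int(round(frac_de * n_contigs))
    n_up = n_de // 2
    n_down = n_de - n_up
    lineage = (
        "superkingdom:Eukaryota;kingdom:Fungi;phylum:Ascomycota;"
        "genus:Calibrationia;species:Calibrationia simulata"
    )
    clades = [
        CladeSpec(
            "ee_bg", "tax_cal", lineage, n_contigs - n_de, "stable",
            base_mean=base_mean, dispersion=dispersion,
        )
    ]
    if n_up:
        clades.append(
            CladeSpec(
                "de_up", "tax_cal", lineage, n_up, "up_in_treatment",
                base_mean=base_mean, dispersion=dispersion, fold_change=fold,
            )
        )
    if n_down:
        clades.append(
            CladeSpec(
                "de_down", "tax_cal", lineage, n_down, "down_in_treatment",
                base_mean=base_mean, dispersion=dispersion, fold_change=fold,
            )
        )
    return ScenarioConfig(
        seed=seed,
        n_replicates_per_condition=n_replicates,
        clades=tuple(clades),
        fraction_unknown=0.0,
        decoys=DecoySpec(fraction_with_decoys=0.0),
        polycistron=PolycistronSpec(n_contigs=0),
        mean_lognorm_sigma=mean_sigma,
    )
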