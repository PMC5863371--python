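"""Taxon-partitioned DE summaries, Krona-style exports and the
end-to-end pipeline driver.

The headline statistic of this kind of study is the presence/abundance
split per taxon: among DE contigs present in both conditions, which
fraction is up in each condition; among condition-exclusive DE contigs,
which condition holds them. Stage order of the driver: filter ->
normalize -> DE -> annotate -> partition -> decode -> report, with a
manifest recording inputs, parameters and per-stage row counts.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .abundance import median_ratio_size_factors, percentile_filter, tpm_table
from .annotate import (
    AnnotationCall,
    TaxonNode,
    TierConfig,
    cascade_annotate,
    resolve_lineage,
    select_annotation,
    taxonomic_rollup,
)
from .core import RANK_ORDER, CountMatrix, TaxonomyTable
from .diffexpr import (
    CONTROL_ONLY,
    PRESENT_BOTH,
    TREATMENT_ONLY,
    de_table,
    fit_eb_nb,
    ma_table,
)
from .polycistron import build_operon, find_orfs, flag_duplicates
from .simulate import orf_query_id

UNKNOWN_BUCKET = "Unknown"
UNCLASSIFIED_BUCKET = "unclassified"


def presence_split_summary(
    de_results: pd.DataFrame,
    calls: dict[str, AnnotationCall],
    taxonomy: TaxonomyTable,
    rank: str = "kingdom",
) -> pd.DataFrame:
    """Per-taxon DE partition at the chosen rank.

    Rows are taxa at ``rank`` plus an ``Unknown`` bucket (unannotated
    contigs) and, where lineages lack the rank, an ``unclassified``
    bucket. Counts: n_DE, direction splits, exclusives; fractions are
    reported among present-in-both and among exclusive contigs and are
    NaN for empty denominators.
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANK_ORDER}")
    de = de_results[de_results["de_call"]]
    acc: dict[str, dict[str, float]] = {}
    for cid, row in de.iterrows():
        call = calls.get(cid)
        if call is None or call.status != "annotated":
            taxon = UNKNOWN_BUCKET
        else:
            call = resolve_lineage(call, taxonomy)
            taxon = call.resolved_lineage.name_at(rank) or UNCLASSIFIED_BUCKET
        rec = acc.setdefault(
            taxon,
            {
                "n_DE": 0,
                "n_up_treatment": 0,
                "n_up_control": 0,
                "n_present_both": 0,
                "n_exclusive_treatment": 0,
                "n_exclusive_control": 0,
                "total_mean_tpm_control": 0.0,
                "total_mean_tpm_treatment": 0.0,
            },
        )
        rec["n_DE"] += 1
        up_treatment = row["log2_fc"] > 0
        rec["n_up_treatment" if up_treatment else "n_up_control"] += 1
        presence = row["presence_class"]
        if presence == PRESENT_BOTH:
            rec["n_present_both"] += 1
            rec.setdefault("n_both_up_treatment", 0)
            rec.setdefault("n_both_up_control", 0)
            rec["n_both_up_treatment" if up_treatment else "n_both_up_control"] += 1
        elif presence == TREATMENT_ONLY:
            rec["n_exclusive_treatment"] += 1
        elif presence == CONTROL_ONLY:
            rec["n_exclusive_control"] += 1
        rec["total_mean_tpm_control"] += row["mean_tpm_control"]
        rec["total_mean_tpm_treatment"] += row["mean_tpm_treatment"]
    rows = []
    for taxon, rec in sorted(acc.items()):
        n_both = rec["n_present_both"]
        n_excl = rec["n_exclusive_treatment"] + rec["n_exclusive_control"]
        rows.append(
            {
                "taxon": taxon,
                **{k: rec.get(k, 0) for k in (
                    "n_DE", "n_up_treatment", "n_up_control", "n_present_both",
                    "n_both_up_treatment", "n_both_up_control",
                    "n_exclusive_treatment", "n_exclusive_control",
                )},
                "frac_both_up_treatment": (
                    rec.get("n_both_up_treatment", 0) / n_both if n_both else float("nan")
                ),
                "frac_both_up_control": (
                    rec.get("n_both_up_control", 0) / n_both if n_both else float("nan")
                ),
                "frac_exclusive_treatment": (
                    rec["n_exclusive_treatment"] / n_excl if n_excl else float("nan")
                ),
                "frac_exclusive_control": (
                    rec["n_exclusive_control"] / n_excl if n_excl else float("nan")
                ),
                "total_mean_tpm_control": rec["total_mean_tpm_control"],
                "total_mean_tpm_treatment": rec["total_mean_tpm_treatment"],
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# Krona export

def _node_dict(node: TaxonNode) -> dict:
    return {
        "name": node.name,
        "rank": node.rank,
        "n_contigs": node.n_contigs,
        "total_tpm": round(node.total_tpm, 6),
        "mean_tpm": round(node.total_tpm / node.n_contigs, 6) if node.n_contigs else 0.0,
        "children": [_node_dict(c) for c in node.children.values()],
    }


def krona_export(root: TaxonNode, json_path, text_path) -> None:
    """Write the taxonomy tree as nested JSON and as Krona text import
    lines (``count<TAB>name1<TAB>name2...``), one line per node holding
    contigs that terminate there."""
    with open(json_path, "w") as fh:
        json.dump(_node_dict(root), fh, indent=2)
        fh.write("\n")
    with open(text_path, "w") as fh:
        for path, node in root.walk():
            if not path:
                continue
            terminal = node.n_contigs - sum(
                c.n_contigs for c in node.children.values()
            )
            if terminal > 0:
                fh.write(str(terminal) + "\t" + "\t".join(path) + "\n")


def read_krona_text(path) -> dict[tuple[str, ...], int]:
    """Re-parse Krona text lines into cumulative per-path contig counts
    (each terminal count contributes to every prefix of its path)."""
    totals: dict[tuple[str, ...], int] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            count = int(fields[0])
            path_names = tuple(fields[1:])
            for i in range(1, len(path_names) + 1):
                key = path_names[:i]
                totals[key] = totals.get(key, 0) + count
    return totals


# ---------------------------------------------------------------------------
# Pipeline driver

@dataclass
class PipelineConfig:
    counts: str
    lengths: str
    self_scores: str
    taxonomy: str
    hits_by_tier: dict[int, str] = field(default_factory=dict)
    contigs: str | None = None
    operons: str | None = None
    outdir: str = "metatriage_out"
    min_total: int | None = 29
    percentile: float | None = None
    ppde_threshold: float = 0.95
    epsilon: float | None = None
    secondary_window: float = 10.0
    report_rank: str = "kingdom"
    min_aa: int = 100
    max_rounds: int = 5
    seed: int = 0

    @classmethod
    def from_dir(cls, indir, outdir="metatriage_out", **kwargs) -> "PipelineConfig":
        """Build a config from a scenario directory using the generator's
        conventional file names."""
        indir = Path(indir)
        tiers = {}
        for p in sorted(indir.glob("hits_tier*.tsv")):
            tiers[int(p.stem.removeprefix("hits_tier"))] = str(p)
        return cls(
            counts=str(indir / "counts.tsv"),
            lengths=str(indir / "lengths.tsv"),
            self_scores=str(indir / "self_scores.tsv"),
            taxonomy=str(indir / "taxonomy.tsv"),
            hits_by_tier=tiers,
            contigs=str(indir / "contigs.fasta"),
            operons=str(indir / "operons.tsv"),
            outdir=str(outdir),
            **kwargs,
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "hits_by_tier" in raw:
            raw["hits_by_tier"] = {int(k): v for k, v in raw["hits_by_tier"].items()}
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and persist the artifacts; returns the
    manifest (also written to ``manifest.json``). Raises on any stage
    failure, with the manifest recording the failing stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {
        "min_total": config.min_total,
        "percentile": config.percentile,
        "ppde_threshold": config.ppde_threshold,
        "epsilon": config.epsilon,
        "secondary_window": config.secondary_window,
        "report_rank": config.report_rank,
        "min_aa": config.min_aa,
        "max_rounds": config.max_rounds,
        "seed": config.seed,
    }, "inputs": {}, "stages": {}}
    stage = "read_inputs"
    try:
        for name in ("counts", "lengths", "self_scores", "taxonomy", "contigs", "operons"):
            p = getattr(config, name)
            if p is None:
                continue
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        for tier, p in sorted(config.hits_by_tier.items()):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")
            manifest["inputs"][f"hits_tier{tier}"] = {"path": str(p), "sha256": _sha256(p)}

        counts = mio.read_counts(config.counts)
        lengths = mio.read_lengths(config.lengths)
        self_scores = mio.read_self_scores(config.self_scores)
        taxonomy = mio.read_taxonomy(config.taxonomy)
        hits_by_tier = {
            tier: mio.read_hits(p, tier) for tier, p in sorted(config.hits_by_tier.items())
        }
        contigs = mio.read_fasta(config.contigs) if config.contigs else None
        operon_ref = (
            mio.read_operon_reference(config.operons) if config.operons else None
        )
        manifest["stages"]["read_inputs"] = {"n_contigs": len(counts.contig_ids)}

        stage = "filter"
        if config.percentile is not None:
            filtered, threshold = percentile_filter(counts, percentile=config.percentile)
        else:
            filtered, threshold = percentile_filter(
                counts, absolute_min=config.min_total if config.min_total is not None else 29
            )
        manifest["stages"]["filter"] = {
            "threshold": threshold,
            "n_kept": len(filtered.contig_ids),
        }

        stage = "normalize"
        factors = median_ratio_size_factors(filtered)
        abundance = tpm_table(filtered, lengths)
        manifest["stages"]["normalize"] = {
            "method": factors.method,
            "factors": {s: round(float(v), 6) for s, v in factors.factors.items()},
        }

        stage = "de"
        hyper, ppde = fit_eb_nb(filtered, factors, max_rounds=config.max_rounds)
        de = de_table(
            filtered, factors, abundance, hyper, ppde,
            threshold=config.ppde_threshold, epsilon=config.epsilon,
        )
        de.to_csv(outdir / "de_results.tsv", sep="\t", float_format="%.6g")
        ma = ma_table(filtered, factors, epsilon=config.epsilon)
        ma.to_csv(outdir / "ma_table.tsv", sep="\t", float_format="%.6g")
        manifest["stages"]["de"] = {
            "n_de": int(de["de_call"].sum()),
            "alpha": round(hyper.alpha, 6),
            "beta": round(hyper.beta, 6),
            "pi": round(hyper.pi, 6),
            "converged": hyper.converged,
        }

        stage = "annotate"
        tier_config = TierConfig(secondary_window=config.secondary_window)
        de_flags = de["de_call"].to_dict()
        contig_hits = {
            tier: [h for h in hits if "|" not in h.query_id]
            for tier, hits in hits_by_tier.items()
        }
        calls = cascade_annotate(
            filtered.contig_ids, contig_hits, self_scores, tier_config, de_flags
        )
        _write_annotation_tsv(calls, taxonomy, outdir / "annotation.tsv")
        manifest["stages"]["annotate"] = {
            "n_annotated": sum(1 for c in calls.values() if c.status == "annotated"),
            "n_unknown": sum(1 for c in calls.values() if c.status == "unknown"),
        }

        stage = "partition"
        mean_tpm = abundance.tpm.mean(axis=1).to_dict()
        tree = taxonomic_rollup(calls, taxonomy, mean_tpm)
        krona_export(tree, outdir / "krona.json", outdir / "krona.txt")
        summary = presence_split_summary(de, calls, taxonomy, rank=config.report_rank)
        summary.to_csv(outdir / "partition_summary.tsv", sep="\t", float_format="%.6g")
        manifest["stages"]["partition"] = {
            "rank": config.report_rank,
            "n_taxa": len(summary),
        }

        stage = "decode"
        operon_rows = []
        all_orfs = []
        if contigs is not None and operon_ref is not None:
            orf_hits: dict[str, list] = {}
            for tier, hits in hits_by_tier.items():
                for h in hits:
                    if "|" in h.query_id:
                        orf_hits.setdefault(h.query_id, []).append(h)
            bacterial = [
                cid
                for cid, call in calls.items()
                if call.status == "annotated"
                and resolve_lineage(call, taxonomy).resolved_lineage.name_at(
                    "superkingdom"
                )
                == "Bacteria"
                and cid in contigs
            ]
            tier1 = tier_config.tiers[0]
            for cid in bacterial:
                orfs = find_orfs(cid, contigs[cid], min_aa=config.min_aa)
                labeled = []
                for orf in orfs:
                    qid = orf_query_id(cid, orf.start, orf.end, orf.strand)
                    hits = orf_hits.get(qid)
                    symbol = None
                    if hits and qid in self_scores:
                        sel = select_annotation(
                            hits, self_scores[qid], tier1, config.secondary_window
                        )
                        if sel is not None:
                            symbol = sel[0][0].subject_description
                    labeled.append(
                        orf if symbol is None else _with_symbol(orf, symbol)
                    )
                all_orfs.extend(labeled)
                if any(o.gene_symbol for o in labeled):
                    operon_rows.extend(build_operon(labeled, operon_ref))
            if operon_rows:
                operon_rows = flag_duplicates(operon_rows)
            mio.write_gff3(all_orfs, outdir / "orfs.gff3")
            _write_operon_tsv(operon_rows, outdir / "operons_decoded.tsv")
        manifest["stages"]["decode"] = {
            "n_orfs": len(all_orfs),
            "n_operons": len(operon_rows),
        }

        stage = "report"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise
    return manifest


def _with_symbol(orf, symbol):
    from dataclasses import replace

    return replace(orf, gene_symbol=symbol)


def _write_annotation_tsv(calls, taxonomy, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tstatus\ttier\tprimary_subject\tprimary_description\t"
            "primary_taxon\tprimary_pmpb\tdemoted\tlineage\tsecondary\n"
        )
        for cid, call in calls.items():
            if call.status != "annotated":
                fh.write(f"{cid}\tunknown\t\t\t\t\t\t\t\t\n")
                continue
            call = resolve_lineage(call, taxonomy)
            sec = ";".join(
                f"{h.subject_id}({p:.1f})" for h, p in call.secondary
            )
            fh.write(
                "\t".join(
                    [
                        cid,
                        "annotated",
                        str(call.tier),
                        call.primary.subject_id,
                        call.resolved_description,
                        call.primary.subject_taxon,
                        f"{call.primary_pmpb:.2f}",
                        str(call.demoted).lower(),
                        str(call.resolved_lineage),
                        sec,
                    ]
                )
                + "\n"
            )


def _write_operon_tsv(operon_calls, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tstrand\tchain\tmatch_status\tmatched_operon\t"
            "mixed_strand\tn_unlabeled\tduplicate_group\trepresentative\n"
        )
        for call in operon_calls:
            fh.write(
                "\t".join(
                    [
                        call.contig_id,
                        call.strand,
                        call.chain,
                        call.match_status,
                        call.matched_operon_id or "",
                        str(call.mixed_strand).lower(),
                        str(call.n_unlabeled),
                        "" if call.duplicate_group is None else str(call.duplicate_group),
                        str(call.is_representative).lower(),
                    ]
                )
                + "\n"
            )
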