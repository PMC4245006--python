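"""End-to-end pipeline: structure → identity → consensus → motifs → tree.

Drives the full comparative analysis from a config (YAML or constructed in
code) and writes the report tables as TSV, gene models as GFF3 and the
tree as Newick.  All randomness flows from the single configured seed and
no timestamps are written, so re-running an identical config reproduces
byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    Group,
    OrthostructError,
    SequenceRecord,
    ValidationError,
    read_fasta,
    write_gene_models_gff3,
)
from .gene_structure import (
    classify_protosplice,
    compute_phases,
    infer_gene_model,
    map_exon_correspondence,
    phase_spectrum,
)
from .motif_domains import (
    annotate_architecture,
    compare_nbd_halves,
    find_conserved_motifs,
    motif_distance_table,
)
from .phylogeny import bootstrap_support, to_newick
from .protein_consensus import (
    IDENTITY_FOOTNOTE,
    build_consensus,
    deletion_tracks,
    identity_matrix,
    progressive_msa,
)
from .synthetic_data import EvolutionConfig, simulate_family

logger = logging.getLogger(__name__)


class StageError(OrthostructError):
    """A pipeline stage failed; the message is stage-labelled."""


@dataclass
class PipelineConfig:
    """Inputs, taxa metadata and stage parameters for one run."""

    output_dir: str
    reference_species: str
    seed: int = 0
    simulate: dict | None = None           # EvolutionConfig kwargs
    genomic_fasta: str | None = None
    cdna_fasta: str | None = None
    protein_fasta: str | None = None
    groups: dict[str, str] = field(default_factory=dict)
    bootstrap_reps: int = 200
    spacing_tolerance: float = 0.25
    correspondence_tolerance: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _load_inputs(config: PipelineConfig):
    """Return (genomic, cdna, protein) dicts keyed by species."""
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        bundle = simulate_family(EvolutionConfig(**sim))
        genomic = {t.genomic.species: t.genomic for t in bundle.taxa}
        cdna = {t.cdna.species: t.cdna for t in bundle.taxa}
        protein = {t.protein.species: t.protein for t in bundle.taxa}
        return genomic, cdna, protein
    if not (config.genomic_fasta and config.cdna_fasta
            and config.protein_fasta):
        raise ValidationError(
            "config needs either a simulate block or all three FASTA paths")

    def load(path: str, alphabet: str) -> dict[str, SequenceRecord]:
        out = {}
        for rec in read_fasta(path, alphabet):
            species = rec.species or rec.id
            if species in config.groups:
                rec.group = Group(config.groups[species])
            out[species] = rec
        return out

    return (load(config.genomic_fasta, "dna"),
            load(config.cdna_fasta, "dna"),
            load(config.protein_fasta, "protein"))


def summarize_structure(models: dict, groups: dict[str, Group]) -> pd.DataFrame:
    """Per-species exon/intron counts and sizes plus group means.

    Group mean intron size is reported both as mean-of-totals divided by
    mean-of-counts and as the pooled per-intron mean, because the two
    summaries differ whenever intron counts vary across species.
    """
    rows = []
    for species, model in models.items():
        rows.append({
            "species": species,
            "group": groups[species].value,
            "n_exons": model.n_exons,
            "n_introns": model.n_introns,
            "exon_bp_total": model.spliced_length,
            "intron_bp_total": model.intron_bp_total,
            "mean_intron_bp": (model.intron_bp_total / model.n_introns
                               if model.n_introns else 0.0),
        })
    df = pd.DataFrame(rows)
    group_rows = []
    for group, sub in df.groupby("group"):
        mean_total = sub["intron_bp_total"].mean()
        mean_count = sub["n_introns"].mean()
        total_bp = sub["intron_bp_total"].sum()
        total_n = sub["n_introns"].sum()
        group_rows.append({
            "species": f"<{group} mean>",
            "group": group,
            "n_exons": sub["n_exons"].mean(),
            "n_introns": mean_count,
            "exon_bp_total": sub["exon_bp_total"].mean(),
            "intron_bp_total": mean_total,
            "mean_intron_bp": (mean_total / mean_count if mean_count else 0.0),
            "pooled_mean_intron_bp": (total_bp / total_n if total_n else 0.0),
        })
    return pd.concat([df, pd.DataFrame(group_rows)], ignore_index=True)


def _tsv(df: pd.DataFrame, path: Path, footer: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=False)
    if footer:
        with open(path, "a") as fh:
            fh.write(f"# {footer}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of key results.

    Writes structure.tsv, gene_models.gff3, identity_{dna,cdna,protein}.tsv,
    phase_spectrum.tsv, protosplice.tsv, similarity_plot.tsv, deletions.tsv,
    motifs.tsv, motif_distances.tsv, nbd_compare.tsv, conserved_motifs.tsv,
    tree.nwk and run.log under the configured output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, footer: str | None = None) -> None:
        path = out / name
        _tsv(df, path, footer)
        written.append(path)

    try:
        genomic, cdna, protein = _load_inputs(config)
        species_list = list(genomic)
        if config.reference_species not in species_list:
            raise ValidationError(
                f"reference species {config.reference_species!r} not among "
                f"taxa {species_list}")
        groups = {s: genomic[s].group for s in species_list}
        if any(g is Group.UNKNOWN for g in groups.values()):
            missing = [s for s, g in groups.items() if g is Group.UNKNOWN]
            raise ValidationError(f"taxa without group assignment: {missing}")

        stage = "structure"
        models = {}
        for s in species_list:
            model = infer_gene_model(cdna[s], genomic[s])
            compute_phases(model)
            classify_protosplice(model, genomic[s])
            models[s] = model
        write_gene_models_gff3(list(models.values()), out / "gene_models.gff3")
        written.append(out / "gene_models.gff3")
        summary = summarize_structure(models, groups)
        detail = pd.DataFrame([{
            "species": s,
            "phases": ",".join(str(i.phase) for i in models[s].introns),
            "proto_classes": ",".join(str(i.proto_class)
                                      for i in models[s].introns),
        } for s in species_list])
        emit(summary.merge(detail, on="species", how="left"),
             "structure.tsv")
        results["models"] = models

        stage = "identity"
        for name, recs in (("dna", genomic), ("cdna", cdna),
                           ("protein", protein)):
            m = identity_matrix([recs[s] for s in species_list])
            m.insert(0, "id", m.index)
            emit(m, f"identity_{name}.tsv", IDENTITY_FOOTNOTE)

        stage = "phases"
        spectrum = phase_spectrum(list(models.values()))
        corr = map_exon_correspondence(
            models, cdna, config.reference_species,
            tolerance=config.correspondence_tolerance)
        # distinct-position spectrum: one intron per conserved reference
        # position plus every gain
        ref_model = models[config.reference_species]
        ref_phase = {p: i.phase for p, i in
                     zip(ref_model.junctions_cdna(), ref_model.introns)}
        distinct_counts = [0, 0, 0]
        for p in corr.conserved:
            distinct_counts[ref_phase[p]] += 1
        emit(pd.DataFrame([
            {"denominator": "pooled", "phase0": spectrum["counts"][0],
             "phase1": spectrum["counts"][1], "phase2": spectrum["counts"][2],
             "chi2_stat": spectrum["chi2_stat"],
             "chi2_p": spectrum["chi2_p"],
             "binom_p_phase0": spectrum["binom_p_phase0"]},
            {"denominator": "distinct_conserved",
             "phase0": distinct_counts[0], "phase1": distinct_counts[1],
             "phase2": distinct_counts[2], "chi2_stat": np.nan,
             "chi2_p": np.nan, "binom_p_phase0": np.nan},
        ]), "phase_spectrum.tsv")
        results["phase_spectrum"] = spectrum
        results["correspondence"] = corr

        proto_rows = []
        counts: dict[str, int] = {}
        for s in species_list:
            for intron in models[s].introns:
                cls = intron.proto_class or "unclassified"
                counts[cls] = counts.get(cls, 0) + 1
        total = sum(counts.values())
        for cls, c in sorted(counts.items()):
            proto_rows.append({"class": cls, "count": c,
                               "fraction": c / total})
        emit(pd.DataFrame(proto_rows), "protosplice.tsv")
        results["protosplice_counts"] = counts

        stage = "consensus"
        msa = progressive_msa([protein[s] for s in species_list])
        profile = build_consensus(msa, config.reference_species)
        emit(profile.to_dataframe(), "similarity_plot.tsv")
        tracks = deletion_tracks(msa, profile)
        emit(pd.DataFrame([
            {"species": s, "start": st, "length": ln}
            for s, runs in tracks.items() for st, ln in runs
        ], columns=["species", "start", "length"]), "deletions.tsv")
        results["msa"] = msa
        results["profile"] = profile

        stage = "motifs"
        archs = {}
        motif_rows = []
        nbd_rows = []
        for s in species_list:
            arch = annotate_architecture(protein[s])
            archs[s] = arch
            for h in arch.nbd1_hits + arch.nbd2_hits:
                motif_rows.append({
                    "species": s, "domain": h.domain, "motif": h.name,
                    "start": h.start + 1, "end": h.end,  # 1-based report
                    "matched": h.matched,
                })
            cmp_res = compare_nbd_halves(protein[s], arch)
            nbd_rows.append({
                "species": s,
                "nbd_identity": cmp_res["identity"],
                "n_conservative": sum(1 for r in cmp_res["records"]
                                      if r.klass == "conservative"),
                "n_radical": sum(1 for r in cmp_res["records"]
                                 if r.klass == "radical"),
            })
        emit(pd.DataFrame(motif_rows), "motifs.tsv")
        emit(pd.DataFrame(nbd_rows), "nbd_compare.tsv", IDENTITY_FOOTNOTE)
        hits_by_species = {s: archs[s].nbd1_hits + archs[s].nbd2_hits
                           for s in species_list}
        dist_table, dist_summary = motif_distance_table(hits_by_species)
        emit(dist_table.reset_index(), "motif_distances.tsv")
        emit(dist_summary.reset_index(), "motif_distance_ranges.tsv")
        group_motifs = find_conserved_motifs(msa)
        emit(pd.DataFrame([{
            "group": gm.group, "start_column": gm.start + 1,
            "end_column": gm.end, "consensus": gm.consensus,
        } for gm in group_motifs],
            columns=["group", "start_column", "end_column", "consensus"]),
            "conserved_motifs.tsv")
        results["architectures"] = archs
        results["group_motifs"] = group_motifs

        stage = "tree"
        tree = bootstrap_support(msa, n_reps=config.bootstrap_reps,
                                 seed=config.seed)
        (out / "tree.nwk").write_text(to_newick(tree) + "\n")
        written.append(out / "tree.nwk")
        results["tree"] = tree

        log_lines = [
            f"orthostruct {__version__}",
            f"seed {config.seed}",
            f"reference {config.reference_species}",
            f"taxa {','.join(species_list)}",
            f"bootstrap_reps {config.bootstrap_reps}",
            f"spacing_tolerance {config.spacing_tolerance}",
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
    except OrthostructError as exc:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise StageError(f"[{stage}] {exc}") from exc
    return results
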