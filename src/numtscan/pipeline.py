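"""End-to-end orchestration: simulate -> repeats -> distances -> classify -> errors.

One reproducible run driven by a single :class:`RunConfig`.  Every stage
writes its artifacts under the output directory; the closing markdown
report only juxtaposes numbers already present in stage artifacts.
Outputs are pure functions of config + seed (the global seed expands to
per-stage seeds by fixed offsets, so stages can be rerun independently).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .classify import (
    build_network,
    call_heteroplasmy,
    call_numts,
    partition_clades,
)
from .distances import AlignedSet, k2p_matrix, net_divergence, group_mean_divergence
from .errors import ErrorModel
from .motifs import MotifInventory
from .repeats import decompose, structure_summary
from .simulate import SimulationConfig, parse_clone_id, simulate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("numtscan")

_ALL_STAGES = ("simulate", "repeats", "distances", "classify", "errors", "report")
_SIM_SEED_OFFSET = 1  # per-stage seed = global seed + fixed offset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, completed: Mapping[str, str], cause: Exception):
        self.stage = stage
        self.completed = dict(completed)
        super().__init__(
            f"stage {stage!r} failed: {cause}; completed artifacts: "
            + (", ".join(self.completed.values()) or "none")
        )


@dataclass
class RunConfig:
    """Parameters of one pipeline run; round-trips through JSON unchanged."""

    seed: int = 0
    outdir: str = "numtscan_run"
    stages: tuple[str, ...] = _ALL_STAGES
    simulation: SimulationConfig | None = None
    clones_fasta: str | None = None
    alignment_fasta: str | None = None
    mask: tuple[int, int] | None = None  # half-open column range of the R2 block
    inventory_tsv: str | None = None
    n_anchor_individuals: int = 5
    min_ratio: float = 5.0
    het_method: str = "site_support"
    taq_rate: float = 7.2e-5
    cycles: int = 34
    error_length: int | None = None  # default: number of unmasked columns
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("stages"):
            d["stages"] = tuple(d["stages"])
        if d.get("mask"):
            d["mask"] = tuple(d["mask"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns a summary dict with artifact paths.

    Any stage failure raises :class:`PipelineError` naming the stage and
    listing the artifacts already written.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {"artifacts": artifacts}
    config.to_json(outdir / "run_config.json")

    stages = config.stages
    dataset = None
    aligned: AlignedSet | None = None
    clone_meta: dict[str, tuple[str, str, str]] = {}  # id -> taxon, individual, size class
    decs = None
    dm = None
    inventory = (
        MotifInventory.from_tsv(config.inventory_tsv) if config.inventory_tsv else None
    )

    def _load_inputs():
        nonlocal aligned
        sequences: dict[str, str] = {}
        if config.clones_fasta:
            from Bio import SeqIO

            for rec in SeqIO.parse(config.clones_fasta, "fasta"):
                sequences[rec.id] = str(rec.seq).upper()
        if config.alignment_fasta:
            mask = range(*config.mask) if config.mask else ()
            aligned = AlignedSet.from_fasta(config.alignment_fasta, mask)
        return sequences

    try:
        stage = "simulate"
        if "simulate" in stages:
            sim_cfg = config.simulation or SimulationConfig()
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed + _SIM_SEED_OFFSET)
            log.info("simulating dataset (seed %d)", sim_cfg.seed)
            dataset = simulate_dataset(sim_cfg)
            aligned = dataset.aligned
            dataset.write_fasta(outdir / "clones.fasta")
            dataset.write_alignment(outdir / "alignment.fasta")
            dataset.write_truth(outdir / "truth_sequences.tsv", outdir / "truth_individuals.tsv")
            sim_cfg.to_json(outdir / "simulation_config.json")
            artifacts["clones"] = str(outdir / "clones.fasta")
            artifacts["alignment"] = str(outdir / "alignment.fasta")
            sequences = {r.id: r.sequence for r in dataset.clones}
            clone_meta = {r.id: (r.taxon, r.individual, r.size_class) for r in dataset.clones}
        else:
            sequences = _load_inputs()
            for cid in list(sequences) or (aligned.labels if aligned else []):
                try:
                    taxon, ind, sc, _ = parse_clone_id(cid)
                    clone_meta[cid] = (taxon, ind, sc)
                except ValueError:
                    clone_meta[cid] = ("", cid, "")
        if not sequences and aligned is not None:
            sequences = {
                label: seq.replace("-", "")
                for label, seq in zip(aligned.labels, aligned.sequences)
            }

        stage = "repeats"
        if "repeats" in stages:
            log.info("decomposing R2 arrays for %d sequences", len(sequences))
            decs = {
                cid: decompose(seq, inventory) if inventory else decompose(seq)
                for cid, seq in sequences.items()
            }
            taxa_map = {cid: clone_meta.get(cid, ("", "", ""))[0] for cid in decs}
            per_seq, per_taxon = structure_summary(decs, taxa_map)
            per_seq.to_csv(outdir / "structures.tsv", sep="\t", index=False)
            per_taxon.to_csv(outdir / "motif_richness.tsv", sep="\t", index=False)
            artifacts["structures"] = str(outdir / "structures.tsv")
            summary["n_arrays"] = int((per_seq["n_units"] > 0).sum())

        stage = "distances"
        if "distances" in stages:
            if aligned is None:
                raise ValueError("distances stage requires an alignment")
            log.info("K2P distances over %d sequences", len(aligned.labels))
            dm = k2p_matrix(aligned)
            dm.to_tsv(outdir / "distances.tsv")
            dm.to_phylip(outdir / "distances.phy")
            artifacts["distances"] = str(outdir / "distances.tsv")

        stage = "classify"
        if "classify" in stages:
            if dm is None or decs is None:
                raise ValueError("classify stage requires distances and repeats stages")
            part = partition_clades(dm, min_ratio=config.min_ratio)
            pd.DataFrame(
                {"id": part.labels, "clade": part.clades}
            ).to_csv(outdir / "clades.tsv", sep="\t", index=False)
            (outdir / "dendrogram.nwk").write_text(part.to_newick() + "\n")
            anchors = (
                dataset.suggest_anchors(config.n_anchor_individuals) if dataset is not None else []
            )
            core = aligned.core_sequences()
            report = call_numts(part, decs, anchors, aligned_core=core)
            calls_json = {
                "anchors": anchors,
                "warnings": list(report.warnings),
                "clades": [dataclasses.asdict(c) for c in report.calls],
            }
            _json_dump(calls_json, outdir / "numt_calls.json")
            artifacts["numt_calls"] = str(outdir / "numt_calls.json")

            # divergence summaries between clades
            groups = part.groups()
            div = []
            for a in sorted(groups):
                for b in sorted(groups):
                    if a < b:
                        div.append(
                            {
                                "clade_a": a,
                                "clade_b": b,
                                "net_divergence": net_divergence(dm, groups[a], groups[b]),
                                "mean_divergence": group_mean_divergence(dm, groups[a], groups[b]),
                            }
                        )
            pd.DataFrame(div).to_csv(outdir / "clade_divergence.tsv", sep="\t", index=False)

            # per-clade haplotype networks over core sequences
            edges_rows = []
            for cid, members in groups.items():
                haps: dict[str, list[str]] = {}
                for m in members:
                    haps.setdefault(core[m], []).append(m)
                named = {f"clade{cid}_h{i + 1}": s for i, (s, _) in enumerate(haps.items())}
                mult = {
                    f"clade{cid}_h{i + 1}": len(ms)
                    for i, (_, ms) in enumerate(haps.items())
                }
                taxa_counts = {}
                for i, (_, ms) in enumerate(haps.items()):
                    counts: dict[str, int] = {}
                    for m in ms:
                        t = clone_meta.get(m, ("",))[0]
                        counts[t] = counts.get(t, 0) + 1
                    taxa_counts[f"clade{cid}_h{i + 1}"] = counts
                net = build_network(named, mult, taxa_counts)
                net.to_graphml(outdir / f"network_clade{cid}.graphml")
                for u, v, w in net.edge_list():
                    edges_rows.append({"clade": cid, "a": u, "b": v, "steps": w})
            pd.DataFrame(edges_rows).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)

            # heteroplasmy on mtDNA-verdict clones, per individual
            mt_clades = set(report.mtdna_clades)
            em_len = config.error_length or sum(aligned.column_keep())
            em = ErrorModel(config.taq_rate, em_len, config.cycles)
            by_ind: dict[str, list[str]] = {}
            for cid2, members in groups.items():
                if cid2 in mt_clades:
                    for m in members:
                        by_ind.setdefault(clone_meta.get(m, ("", m, ""))[1], []).append(m)
            het_calls = []
            for ind in sorted(by_ind):
                ids = by_ind[ind]
                call = call_heteroplasmy(
                    ind,
                    {i: core[i] for i in ids},
                    {i: decs[i] for i in ids},
                    em,
                    method=config.het_method,
                )
                het_calls.append(dataclasses.asdict(call))
            _json_dump({"individuals": het_calls}, outdir / "heteroplasmy_calls.json")
            artifacts["heteroplasmy_calls"] = str(outdir / "heteroplasmy_calls.json")
            summary["n_clades"] = part.n_clades
            summary["numt_clades"] = list(report.numt_clades)
            summary["n_sequence_het"] = sum(1 for c in het_calls if c["sequence_het"])
            summary["n_length_het"] = sum(1 for c in het_calls if c["length_het"])

        stage = "errors"
        if "errors" in stages:
            length = config.error_length
            if length is None:
                length = sum(aligned.column_keep()) if aligned is not None else 724
            em = ErrorModel(config.taq_rate, int(length), config.cycles)
            err_json = {
                "rate": em.rate,
                "length": em.length,
                "cycles": em.cycles,
                "lambda": em.lam,
                "error_free_fraction": em.error_free_fraction(),
                "tail_fractions": {f">{k}": em.tail_fraction(k) for k in (2, 3, 4)},
                "collapse_threshold": em.collapse_threshold(),
            }
            _json_dump(err_json, outdir / "error_model.json")
            artifacts["error_model"] = str(outdir / "error_model.json")
            summary["lambda"] = em.lam

        stage = "report"
        if "report" in stages:
            _write_report(outdir, artifacts, summary)
            artifacts["report"] = str(outdir / "report.md")
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, artifacts, exc) from exc
    return summary


def _write_report(outdir: Path, artifacts: Mapping[str, str], summary: Mapping) -> None:
    """Markdown report; every number is read back from a stage artifact."""
    lines = ["# numtscan run report", ""]
    if "numt_calls" in artifacts:
        calls = json.loads(Path(artifacts["numt_calls"]).read_text())
        n = len(calls["clades"])
        numt = [c for c in calls["clades"] if c["verdict"] == "numt"]
        lines += [
            f"Clades found: **{n}** (study regime: 3 — one mtDNA, two numt).",
            f"Numt verdicts: **{len(numt)}** "
            f"(sizes {', '.join(str(c['n_members']) for c in numt) or '—'}).",
            "",
            "| clade | verdict | members | repeat-absent fraction | anchor | mean internal steps |",
            "|---|---|---|---|---|---|",
        ]
        for c in calls["clades"]:
            steps = "—" if c["mean_internal_steps"] is None else f"{c['mean_internal_steps']:.2f}"
            lines.append(
                f"| {c['clade']} | {c['verdict']} | {c['n_members']} | "
                f"{c['repeat_absent_fraction']:.2f} | {c['contains_anchor']} | {steps} |"
            )
        lines.append("")
        div_path = outdir / "clade_divergence.tsv"
        if div_path.exists():
            div = pd.read_csv(div_path, sep="\t")
            lines += [
                "Between-clade K2P divergence (net / plain mean). In the study regime the",
                "two numt clades are closer to each other than either is to the mtDNA clade.",
                "",
            ]
            for _, r in div.iterrows():
                lines.append(
                    f"- clades {int(r.clade_a)}–{int(r.clade_b)}: "
                    f"net {r.net_divergence:.3f}, mean {r.mean_divergence:.3f}"
                )
            lines.append("")
    if "heteroplasmy_calls" in artifacts:
        het = json.loads(Path(artifacts["heteroplasmy_calls"]).read_text())["individuals"]
        seq_het = sum(1 for c in het if c["sequence_het"])
        len_het = sum(1 for c in het if c["length_het"])
        lines += [
            f"Heteroplasmy: {seq_het}/{len(het)} individuals with sequence heteroplasmy, "
            f"{len_het}/{len(het)} with length heteroplasmy.",
            "",
        ]
    if "error_model" in artifacts:
        err = json.loads(Path(artifacts["error_model"]).read_text())
        tails = err["tail_fractions"]
        lines += [
            f"Polymerase error model: lambda = {err['lambda']:.2f} errors/clone "
            f"({err['rate']:.1e}/bp/cycle x {err['length']} bp x {err['cycles']} cycles); "
            f"P(>2)={tails['>2']:.0%}, P(>3)={tails['>3']:.0%}, P(>4)={tails['>4']:.0%}; "
            f"expected error-free fraction {err['error_free_fraction']:.0%}.",
            "",
        ]
    (outdir / "report.md").write_text("\n".join(lines))
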