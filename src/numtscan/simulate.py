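"""Synthetic clone-set generator with ground truth.

Emulates the data-generating process behind a cloned control-region
survey of a four-taxon bat species complex:

* a rooted species history ``((East,Hainan),(Central,septentrionalis))``
  preceded by a long stem lineage, with branch lengths in expected
  substitutions/site at the mitochondrial rate;
* one or more ancient translocations of the mitochondrial control region
  into the nuclear genome at points along the stem (at or before the root
  split); each numt lineage loses the R2 repeat array at translocation
  and thereafter evolves at a reduced rate (default 0.1x) down the same
  species history;
* per-individual heteroplasmy: a minor core haplotype differing at one or
  two positions, and multiple R2 size classes produced by replication
  slippage (+-1 unit per event, geometric event count);
* per-clone polymerase errors: Poisson(rate x clone length x cycles)
  uniform substitution errors, emulating Taq misincorporation during PCR
  and cloning.

Every emitted clone has exactly one truth row (origin, haplotype, true
repeat structure, injected error positions), and per-individual truth
flags are defined over the clones actually emitted, so downstream calls
can be scored without ambiguity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import AlignedSet
from .motifs import DEFAULT_INVENTORY, MotifInventory, parse_structure, structure_string

__all__ = [
    "ConfigError",
    "HeteroplasmySimConfig",
    "CloningConfig",
    "SimulationConfig",
    "CloneRecord",
    "SimulatedDataset",
    "simulate_dataset",
    "parse_clone_id",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of A,C,G,T (A<->G, C<->T) as code indices
_TRANSITION = np.array([2, 3, 0, 1])
_DEFAULT_TOPOLOGY = (
    "((East:0.006,Hainan:0.006):0.006,(Central:0.006,septentrionalis:0.006):0.006);"
)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class HeteroplasmySimConfig:
    """Heteroplasmy regime: minor haplotypes and R2 size classes."""

    minor_freq: float = 0.5
    n_core_diffs: int = 2
    het_taxa: tuple[str, ...] = ("East", "Hainan")
    size_class_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.5, 3: 0.15, 4: 0.1}
    )
    slippage_rate: float = 1.0  # probability an extra size class slipped at all
    slippage_geom_p: float = 0.5  # geometric parameter of the event count


@dataclass(frozen=True)
class CloningConfig:
    """Cloning depth and the polymerase error process.

    Clones are picked per individual (as in the lab protocol, where 8-12
    clones are sequenced per PCR fragment); each clone then samples one of
    the individual's R2 size classes, which are only discovered post hoc.
    """

    mt_clones_per_individual: int = 10
    taq_rate: float = 7.2e-5
    cycles: int = 34
    # deterministic per-individual numt clone counts; the 1:4 ratio mirrors
    # the unequal amplification propensities of the two numt loci
    numt_clones: tuple[int, ...] = (1, 4)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    topology: str = _DEFAULT_TOPOLOGY
    root_stem_length: float = 0.3
    core_length: int = 500
    array_position: int = 400
    motif_inventory: MotifInventory = DEFAULT_INVENTORY
    initial_array: str = "(C)18"
    mt_rate_scale: float = 1.0
    numt_rate_factor: float = 0.1
    transition_fraction: float = 0.8
    translocation_events: tuple[tuple[float, str | None], ...] = ((0.7, None), (1.0, None))
    individuals_per_taxon: Mapping[str, int] = field(
        default_factory=lambda: {"East": 7, "Hainan": 4, "Central": 3, "septentrionalis": 4}
    )
    individual_polymorphism: float = 0.002
    heteroplasmy: HeteroplasmySimConfig = field(default_factory=HeteroplasmySimConfig)
    cloning: CloningConfig = field(default_factory=CloningConfig)

    def validate(self) -> None:
        for name in (
            "root_stem_length",
            "mt_rate_scale",
            "individual_polymorphism",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0 < self.numt_rate_factor <= 1):
            raise ConfigError("numt_rate_factor must lie in (0, 1]")
        if not (0 <= self.transition_fraction <= 1):
            raise ConfigError("transition_fraction must lie in [0, 1]")
        for frac, _src in self.translocation_events:
            if frac < 0:
                raise ConfigError("translocation_events time fractions must be >= 0")
        if self.cloning.taq_rate < 0:
            raise ConfigError("cloning.taq_rate must be non-negative")
        if self.cloning.cycles < 0:
            raise ConfigError("cloning.cycles must be non-negative")
        if not (0 <= self.heteroplasmy.minor_freq <= 1):
            raise ConfigError("heteroplasmy.minor_freq must lie in [0, 1]")
        if not (0 <= self.heteroplasmy.slippage_rate <= 1):
            raise ConfigError("heteroplasmy.slippage_rate must lie in [0, 1]")
        if not (0 <= self.array_position <= self.core_length):
            raise ConfigError("array_position must lie within the core")
        taxa = set(self._tree_taxa())
        missing = set(self.individuals_per_taxon) ^ taxa
        if missing:
            raise ConfigError(
                f"topology leaves and individuals_per_taxon disagree on: {sorted(missing)}"
            )

    def _tree(self) -> dendropy.Tree:
        try:
            return dendropy.Tree.get(data=self.topology, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise ConfigError(f"topology is not valid newick: {exc}") from exc

    def _tree_taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree().leaf_node_iter()]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif_inventory"] = {
            "labels": list(self.motif_inventory.labels),
            "units": list(self.motif_inventory.units),
        }
        d["heteroplasmy"]["size_class_weights"] = {
            str(k): v for k, v in self.heteroplasmy.size_class_weights.items()
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "motif_inventory" in d:
            inv = d["motif_inventory"]
            d["motif_inventory"] = MotifInventory(tuple(inv["labels"]), tuple(inv["units"]))
        if "heteroplasmy" in d and isinstance(d["heteroplasmy"], Mapping):
            h = dict(d["heteroplasmy"])
            if "size_class_weights" in h:
                h["size_class_weights"] = {int(k): v for k, v in h["size_class_weights"].items()}
            if "het_taxa" in h:
                h["het_taxa"] = tuple(h["het_taxa"])
            d["heteroplasmy"] = HeteroplasmySimConfig(**h)
        if "cloning" in d and isinstance(d["cloning"], Mapping):
            c = dict(d["cloning"])
            if "numt_clones" in c:
                c["numt_clones"] = tuple(c["numt_clones"])
            d["cloning"] = CloningConfig(**c)
        if "translocation_events" in d:
            d["translocation_events"] = tuple(
                (float(f), s) for f, s in d["translocation_events"]
            )
        return cls(**d)


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone with its provenance."""

    id: str
    taxon: str
    individual: str
    size_class: str
    sequence: str


def parse_clone_id(clone_id: str) -> tuple[str, str, str, str]:
    """Split ``taxon|individual|sizeclass|cloneNN`` into its fields."""
    parts = clone_id.split("|")
    if len(parts) != 4:
        raise ValueError(f"clone id {clone_id!r} is not taxon|individual|sizeclass|cloneNN")
    return tuple(parts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# evolution primitives
# ---------------------------------------------------------------------------

def _substitute(seq: np.ndarray, branch_length: float, rng: np.random.Generator, ti_frac: float) -> np.ndarray:
    """Apply Poisson(branch_length * L) substitution events (with multiple hits)."""
    out = seq.copy()
    n = rng.poisson(branch_length * len(seq))
    if n == 0:
        return out
    sites = rng.integers(0, len(seq), n)
    for site in sites:
        if rng.random() < ti_frac:
            out[site] = _TRANSITION[out[site]]
        else:
            choices = [b for b in range(4) if b != out[site] and b != _TRANSITION[out[site]]]
            out[site] = choices[rng.integers(0, 2)]
    return out


def _evolve_tree(
    tree: dendropy.Tree,
    root_state: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    ti_frac: float,
) -> dict[str, np.ndarray]:
    """Evolve a state down the species tree; returns per-leaf states."""
    states: dict[str, np.ndarray] = {}

    def rec(node, state: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = (child.edge.length or 0.0) * rate
            child_state = _substitute(state, bl, rng, ti_frac)
            if child.is_leaf():
                states[child.taxon.label] = child_state
            else:
                rec(child, child_state)

    rec(tree.seed_node, root_state)
    return states


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    clones: list[CloneRecord]
    aligned: AlignedSet
    truth_sequences: pd.DataFrame
    truth_individuals: pd.DataFrame

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.clones:
                fh.write(f">{rec.id}\n{rec.sequence}\n")

    def write_alignment(self, path) -> None:
        self.aligned.to_fasta(path)

    def write_truth(self, seq_path, ind_path) -> None:
        self.truth_sequences.to_csv(seq_path, sep="\t", index=False)
        self.truth_individuals.to_csv(ind_path, sep="\t", index=False)

    def truth_json(self) -> str:
        return json.dumps(
            {
                "sequences": self.truth_sequences.to_dict(orient="records"),
                "individuals": self.truth_individuals.to_dict(orient="records"),
            },
            indent=2,
        )

    def origin_of(self) -> dict[str, str]:
        return dict(zip(self.truth_sequences["id"], self.truth_sequences["origin"]))

    def suggest_anchors(self, n_individuals: int = 5) -> list[str]:
        """First mtDNA clone of the first n individuals — the synthetic
        analogue of long-range-PCR-verified reference sequences."""
        mt = self.truth_sequences[self.truth_sequences["origin"] == "mtDNA"]
        anchors = []
        for _, group in mt.groupby("individual", sort=False):
            anchors.append(group.iloc[0]["id"])
            if len(anchors) >= n_individuals:
                break
        return anchors


def _slip(units: list[str], rng: np.random.Generator, geom_p: float) -> list[str]:
    """Apply a geometric number of +-1-unit slippage events."""
    out = list(units)
    for _ in range(int(rng.geometric(geom_p))):
        if len(out) > 1 and rng.random() < 0.5:
            del out[rng.integers(0, len(out))]
        else:
            i = int(rng.integers(0, len(out)))
            out.insert(i, out[i])
    return out


def _units_to_structure(units: Sequence[str]) -> str:
    runs: list[tuple[str, int]] = []
    for lab in units:
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1] + 1)
        else:
            runs.append((lab, 1))
    return structure_string(runs)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a clone set, its true-homology alignment and truth tables.

    Deterministic given ``config.seed``.  See the module docstring for the
    generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    inv = config.motif_inventory
    ti = config.transition_fraction

    # ancestral states
    core_anc = rng.integers(0, 4, config.core_length)
    runs = parse_structure(config.initial_array)
    if any(len(lab) > 1 for lab, _ in runs):
        raise ConfigError("initial_array must contain full units only")
    array_anc: list[str] = [lab for lab, count in runs for _ in range(count)]

    # stem lineage with translocation captures (fraction 1 = stem origin)
    events = sorted(
        ((frac, src, k + 1) for k, (frac, src) in enumerate(config.translocation_events)),
        key=lambda e: -e[0],
    )
    top = max([1.0] + [e[0] for e in events])
    state = core_anc
    pos = top
    captured: list[tuple[int, float, np.ndarray]] = []  # (numt index, fraction, core state)
    for frac, _src, k in events:
        bl = (pos - frac) * config.root_stem_length * config.mt_rate_scale
        state = _substitute(state, bl, rng, ti)
        captured.append((k, frac, state.copy()))
        pos = frac
    root_state = _substitute(state, pos * config.root_stem_length * config.mt_rate_scale, rng, ti)

    tree = config._tree()
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    mt_core = _evolve_tree(tree, root_state, config.mt_rate_scale, rng, ti)

    numt_core: dict[int, dict[str, np.ndarray]] = {}
    for k, frac, cap_state in captured:
        stem_bl = frac * config.root_stem_length * config.numt_rate_factor
        at_root = _substitute(cap_state, stem_bl, rng, ti)
        numt_core[k] = _evolve_tree(tree, at_root, config.numt_rate_factor, rng, ti)

    het = config.heteroplasmy
    cloning = config.cloning
    ap = config.array_position
    class_counts = sorted(het.size_class_weights)
    class_probs = np.array([het.size_class_weights[c] for c in class_counts], dtype=float)
    class_probs = class_probs / class_probs.sum()

    clones: list[CloneRecord] = []
    aligned_rows: list[tuple[str, str, str, str]] = []  # id, core5+array, pad marker via len
    truth_rows = []
    ind_rows = []

    for taxon in taxa:
        prefix = taxon[:2].upper()
        for i in range(int(config.individuals_per_taxon[taxon])):
            ind = f"{prefix}{i + 1:02d}"
            major = _substitute(
                mt_core[taxon], config.individual_polymorphism, rng, ti
            )
            is_het = taxon in het.het_taxa and het.minor_freq > 0 and het.n_core_diffs > 0
            minor = None
            if is_het:
                minor = major.copy()
                sites = rng.choice(config.core_length, size=het.n_core_diffs, replace=False)
                for site in sites:
                    shift = 1 + int(rng.integers(0, 3))
                    minor[site] = (minor[site] + shift) % 4
            n_classes = int(rng.choice(class_counts, p=class_probs))
            class_arrays = [array_anc]
            for _ in range(n_classes - 1):
                if het.slippage_rate > 0 and rng.random() < het.slippage_rate:
                    class_arrays.append(_slip(class_arrays[0], rng, het.slippage_geom_p))
                else:
                    class_arrays.append(list(class_arrays[0]))

            class_codes = []
            for units in class_arrays:
                array_seq = "".join(inv.unit(lab) for lab in units)
                arr = np.frombuffer(array_seq.encode(), dtype=np.uint8)
                class_codes.append(np.searchsorted(_BASES, arr))  # ACGT codes

            clone_no = 0
            emitted_haps: set[str] = set()
            emitted_lengths: set[int] = set()
            for _ in range(cloning.mt_clones_per_individual):
                sc_i = int(rng.integers(0, n_classes)) + 1
                units = class_arrays[sc_i - 1]
                arr_codes = class_codes[sc_i - 1]
                arr_len = len(arr_codes)
                clone_no += 1
                use_minor = is_het and rng.random() < het.minor_freq
                core = minor if use_minor else major
                unaligned = np.concatenate([core[:ap], arr_codes, core[ap:]])
                n_err = rng.poisson(cloning.taq_rate * len(unaligned) * cloning.cycles)
                err_sites = sorted(int(s) for s in rng.integers(0, len(unaligned), n_err))
                for site in err_sites:
                    shift = 1 + int(rng.integers(0, 3))
                    unaligned[site] = (unaligned[site] + shift) % 4
                cid = f"{taxon}|{ind}|S{sc_i}|clone{clone_no:02d}"
                seq = _decode(unaligned)
                clones.append(CloneRecord(cid, taxon, ind, f"S{sc_i}", seq))
                aligned_rows.append((cid, seq[: ap + arr_len], seq[ap + arr_len :], ""))
                hap_id = f"{ind}-minor" if use_minor else f"{ind}-major"
                emitted_haps.add(hap_id)
                emitted_lengths.add(arr_len)
                truth_rows.append(
                    {
                        "id": cid,
                        "taxon": taxon,
                        "individual": ind,
                        "origin": "mtDNA",
                        "haplotype": hap_id,
                        "size_class": f"S{sc_i}",
                        "structure": _units_to_structure(units),
                        "array_length": arr_len,
                        "n_errors": int(n_err),
                        "error_positions": ",".join(str(s) for s in err_sites),
                    }
                )

            for k, n_numt in enumerate(cloning.numt_clones, start=1):
                if k not in numt_core:
                    continue
                core = numt_core[k][taxon]
                for _ in range(int(n_numt)):
                    clone_no += 1
                    unaligned = core.copy()
                    n_err = rng.poisson(cloning.taq_rate * len(unaligned) * cloning.cycles)
                    err_sites = sorted(int(s) for s in rng.integers(0, len(unaligned), n_err))
                    for site in err_sites:
                        shift = 1 + int(rng.integers(0, 3))
                        unaligned[site] = (unaligned[site] + shift) % 4
                    cid = f"{taxon}|{ind}|N{k}|clone{clone_no:02d}"
                    seq = _decode(unaligned)
                    clones.append(CloneRecord(cid, taxon, ind, f"N{k}", seq))
                    aligned_rows.append((cid, seq[:ap], seq[ap:], "numt"))
                    truth_rows.append(
                        {
                            "id": cid,
                            "taxon": taxon,
                            "individual": ind,
                            "origin": f"numt-{k}",
                            "haplotype": f"{taxon}-numt-{k}",
                            "size_class": f"N{k}",
                            "structure": "",
                            "array_length": 0,
                            "n_errors": int(n_err),
                            "error_positions": ",".join(str(s) for s in err_sites),
                        }
                    )

            ind_rows.append(
                {
                    "individual": ind,
                    "taxon": taxon,
                    "sequence_het": len(emitted_haps) >= 2,
                    "length_het": len(emitted_lengths) >= 2,
                    "n_size_classes": len(emitted_lengths),
                    "n_mt_clones": sum(
                        1 for r in truth_rows if r["individual"] == ind and r["origin"] == "mtDNA"
                    ),
                }
            )

    truth_sequences = pd.DataFrame(truth_rows)
    truth_individuals = pd.DataFrame(ind_rows)

    # block alignment: core5 | array block (left-justified, right gap-padded,
    # numts all-gap) | core3.  The array block is the mask.
    width = int(truth_sequences["array_length"].max()) if len(truth_sequences) else 0
    labels, seqs = [], []
    for cid, head, tail, kind in aligned_rows:
        arr_len = len(head) - ap
        labels.append(cid)
        seqs.append(head + "-" * (width - arr_len) + tail)
    mask = frozenset(range(ap, ap + width))
    aligned = AlignedSet(labels, seqs, mask)
    return SimulatedDataset(config, clones, aligned, truth_sequences, truth_individuals)
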