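"""Seeded simulator of multi-strain pangenomes with known ground truth.

The generator emulates the structure of a five-strain probiotic pan-proteome:
a shared core present in every strain, accessory families present in a strict
subset of two or more strains, strain-private unique families, and
group-marker families present in every strain of one comparison group (the
cholesterol-assimilating pair) and absent from the other — 21 of them by
default, mirroring the contrast the pipeline is designed to detect. Each
family descends from a random ancestral protein; every carrying strain
receives an independently point-mutated copy (no indels, so expected identity
between copies is analytic: ``(1-r)^2``-ish per pair of branches), and gene
duplication adds a second mutated copy with a small probability.

Nucleotide genomes evolve from a root sequence along a fixed strain tree with
per-branch substitution rates; the expected raw (uncorrected) divergence
between two leaves follows the 4-state uniform-substitution chain:
``75 * (1 - prod(1 - 4 p_b / 3))`` over the branches b on the connecting path,
which is what fragment ANI estimates.

Everything is driven by one ``numpy`` Generator seeded from the config, with a
fixed draw order (families in listed order: length, ancestral sequence, COG
class, presence set, per-strain copies, duplication coin), so outputs are
bit-reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, StrainProteome, write_json, logger
from .ani import GenomeSequence
from .partition import PartitionLabel

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT = np.array(list("ACGT"))

# Rough COG class frequencies for a lactic-acid-bacterium-like proteome:
# carbohydrate transport/metabolism (G) and translation (J) lead, followed by
# amino-acid transport (E), transcription (K), replication/repair (L),
# cell wall/membrane/envelope biogenesis (M), and a tail of smaller classes
# plus "function unknown" (S).
DEFAULT_COG_WEIGHTS: dict[str, float] = {
    "G": 0.14, "J": 0.10, "E": 0.09, "K": 0.08, "L": 0.07, "M": 0.06,
    "P": 0.05, "C": 0.05, "F": 0.04, "H": 0.04, "O": 0.04, "T": 0.04,
    "V": 0.03, "D": 0.02, "N": 0.02, "U": 0.02, "I": 0.02, "Q": 0.01,
    "S": 0.08,
}
DEFAULT_UNANNOTATED_FRACTION = 0.14  # ~ share of hypothetical proteins


@dataclass
class PangenomeConfig:
    """Study conditions for one simulated pangenome.

    Defaults mirror a five-strain probiotic comparison scaled to desk size:
    two cholesterol-assimilating strains versus three general probiotic
    strains, 150 core + 90 accessory + 12 unique-per-strain families, and 21
    group-marker families private to the cholesterol-assimilating pair.
    """

    strains: tuple[str, ...] = ("LR13", "WEFA23", "T110", "170M39", "SP15")
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "hypocholesterolemic": ("LR13", "WEFA23"),
            "general": ("T110", "170M39", "SP15"),
        }
    )
    n_core_families: int = 150
    n_accessory_families: int = 90
    p_accessory_presence: float = 0.5
    n_unique_per_strain: int = 12
    n_group_marker_families: int = 21
    marker_present_group: str = "hypocholesterolemic"
    marker_absent_group: str = "general"
    protein_length_mean: float = 240.0
    protein_length_sd: float = 70.0
    protein_length_min: int = 60
    substitution_rate: float = 0.02
    p_duplication: float = 0.05
    cog_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COG_WEIGHTS))
    unannotated_fraction: float = DEFAULT_UNANNOTATED_FRACTION
    genome_length: int = 50_000
    genome_branch_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_accessory_presence", "p_duplication", "substitution_rate",
                     "unannotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_core_families", "n_accessory_families", "n_unique_per_strain",
                     "n_group_marker_families"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if (
            self.n_core_families
            + self.n_accessory_families
            + self.n_unique_per_strain
            + self.n_group_marker_families
        ) == 0:
            raise ValueError("at least one family category must be non-zero")
        if self.n_group_marker_families:
            a = set(self.groups.get(self.marker_present_group, ()))
            b = set(self.groups.get(self.marker_absent_group, ()))
            if not a or not b:
                raise ValueError("marker groups must be defined and non-empty")
            if a & b:
                raise ValueError("marker groups overlap; group-marker families infeasible")
            if len(a) == 1 and self.n_unique_per_strain:
                raise ValueError(
                    "a single-strain marker group is indistinguishable from "
                    "unique families; use n_unique_per_strain=0 or a larger group"
                )
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids")
        for g, members in self.groups.items():
            stray = set(members) - set(self.strains)
            if stray:
                raise ValueError(f"group {g!r} references unknown strains {sorted(stray)}")
        if self.n_accessory_families and len(self.strains) < 3:
            raise ValueError("accessory families need at least 3 strains")


@dataclass
class FamilyTruth:
    family_id: str
    label: PartitionLabel
    presence: tuple[str, ...]
    cog_class: Optional[str]
    copy_numbers: dict[str, int]
    is_marker: bool = False


@dataclass
class GroundTruth:
    """What the generator actually emitted, keyed by family id."""

    families: dict[str, FamilyTruth]
    marker_ids: list[str]
    strains: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        out = {lab.value: 0 for lab in PartitionLabel}
        for fam in self.families.values():
            out[fam.label.value] += 1
        return out

    def presence_frame(self) -> pd.DataFrame:
        """Boolean family-by-strain presence matrix (sorted family ids)."""
        fids = sorted(self.families)
        data = np.zeros((len(fids), len(self.strains)), dtype=bool)
        col = {s: i for i, s in enumerate(self.strains)}
        for r, fid in enumerate(fids):
            for s in self.families[fid].presence:
                data[r, col[s]] = True
        return pd.DataFrame(data, index=fids, columns=list(self.strains))

    def membership_sets(self) -> set[frozenset[str]]:
        """The true clustering as a set of frozensets of protein ids."""
        out = set()
        for fam in self.families.values():
            members = set()
            for s in fam.presence:
                for c in range(1, fam.copy_numbers[s] + 1):
                    members.add(f"{s}|{fam.family_id}|{c}")
            out.add(frozenset(members))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "strains": list(self.strains),
            "marker_ids": list(self.marker_ids),
            "families": {
                fid: {
                    "label": fam.label.value,
                    "presence": list(fam.presence),
                    "cog_class": fam.cog_class,
                    "copy_numbers": dict(fam.copy_numbers),
                    "is_marker": fam.is_marker,
                }
                for fid, fam in sorted(self.families.items())
            },
        }
        write_json(payload, path)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator, alphabet: np.ndarray = AA
) -> str:
    """Independently substitute each position with probability ``rate``.

    Substitutions are drawn uniformly from the other alphabet letters, so a
    mutated position never retains its original letter; length is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        k = len(alphabet)
        lut = {c: i for i, c in enumerate(alphabet)}
        idx = np.array([lut.get(c, 0) for c in arr[mask]])
        shift = rng.integers(1, k, size=mask.sum())
        arr[mask] = alphabet[(idx + shift) % k]
    return "".join(arr)


def _draw_length(cfg: PangenomeConfig, rng: np.random.Generator) -> int:
    L = int(round(rng.normal(cfg.protein_length_mean, cfg.protein_length_sd)))
    return max(L, cfg.protein_length_min)


def _draw_cog(cfg: PangenomeConfig, rng: np.random.Generator) -> Optional[str]:
    if rng.random() < cfg.unannotated_fraction:
        return None
    classes = sorted(cfg.cog_weights)
    w = np.array([cfg.cog_weights[c] for c in classes], dtype=float)
    return str(rng.choice(np.array(classes), p=w / w.sum()))


def _accessory_presence(
    cfg: PangenomeConfig, rng: np.random.Generator
) -> tuple[str, ...]:
    """Rejection-sample a presence set with 2 <= |presence| <= n-1.

    When group-marker families are configured, the marker presence pattern
    itself is also rejected, so the marker families are by construction the
    only families exclusive to the marker group and the generator's ground
    truth stays unambiguous.
    """
    n = len(cfg.strains)
    marker_pattern: Optional[frozenset[str]] = None
    if cfg.n_group_marker_families:
        marker_pattern = frozenset(cfg.groups[cfg.marker_present_group])
    while True:
        mask = rng.random(n) < cfg.p_accessory_presence
        k = int(mask.sum())
        if not 2 <= k <= n - 1:
            continue
        chosen = tuple(s for s, m in zip(cfg.strains, mask) if m)
        if marker_pattern is not None and frozenset(chosen) == marker_pattern:
            continue
        return chosen


def generate_pangenome(
    config: PangenomeConfig,
) -> tuple[list[StrainProteome], GroundTruth]:
    """Simulate proteomes for every strain plus the emitted ground truth.

    Family ids are F0001... in generation order (core, accessory, unique,
    marker); protein ids are ``<strain>|<family>|<copy>``. Bit-reproducible
    from (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    r = config.substitution_rate
    families: dict[str, FamilyTruth] = {}
    per_strain: dict[str, list[ProteinRecord]] = {s: [] for s in config.strains}
    marker_ids: list[str] = []
    fam_counter = 0

    def emit_family(presence: Sequence[str], label: PartitionLabel, is_marker=False):
        nonlocal fam_counter
        fam_counter += 1
        fid = f"F{fam_counter:04d}"
        length = _draw_length(config, rng)
        ancestral = random_protein(rng, length)
        cog = _draw_cog(config, rng)
        copy_numbers: dict[str, int] = {}
        for strain in config.strains:
            if strain not in presence:
                continue
            n_copies = 1
            if rng.random() < config.p_duplication:
                n_copies = 2
            copy_numbers[strain] = n_copies
            for c in range(1, n_copies + 1):
                seq = mutate_sequence(ancestral, r, rng)
                per_strain[strain].append(
                    ProteinRecord(
                        protein_id=f"{strain}|{fid}|{c}",
                        strain_id=strain,
                        sequence=seq,
                        cog_class=cog,
                    )
                )
        families[fid] = FamilyTruth(
            family_id=fid,
            label=label,
            presence=tuple(s for s in config.strains if s in set(presence)),
            cog_class=cog,
            copy_numbers=copy_numbers,
            is_marker=is_marker,
        )
        return fid

    for _ in range(config.n_core_families):
        emit_family(config.strains, PartitionLabel.CORE)
    for _ in range(config.n_accessory_families):
        emit_family(_accessory_presence(config, rng), PartitionLabel.ACCESSORY)
    for strain in config.strains:
        for _ in range(config.n_unique_per_strain):
            emit_family((strain,), PartitionLabel.UNIQUE)
    if config.n_group_marker_families:
        present = config.groups[config.marker_present_group]
        label = (
            PartitionLabel.CORE
            if set(present) == set(config.strains)
            else (PartitionLabel.UNIQUE if len(present) == 1 else PartitionLabel.ACCESSORY)
        )
        for _ in range(config.n_group_marker_families):
            marker_ids.append(emit_family(present, label, is_marker=True))

    group_of = {
        s: g for g, members in config.groups.items() for s in members
    }
    proteomes = [
        StrainProteome(
            strain_id=s, proteins=per_strain[s], group_label=group_of.get(s)
        )
        for s in config.strains
    ]
    truth = GroundTruth(families=families, marker_ids=marker_ids, strains=config.strains)
    logger.info(
        "generate_pangenome: %d families, %d proteins over %d strains (seed %d)",
        len(families),
        sum(len(p) for p in proteomes),
        len(config.strains),
        config.seed,
    )
    return proteomes, truth


# --- nucleotide genomes -------------------------------------------------------

# Fixed 5-leaf genome tree shape: ((A,B),(C,(D,E))) with one rate per branch;
# generalized below to any strain count by a caterpillar on the remainder.


def _default_tree(strains: Sequence[str]) -> tuple:
    """Nested-tuple tree over strains: leaves are ids, internal nodes pairs."""
    if len(strains) == 1:
        return strains[0]
    if len(strains) == 2:
        return (strains[0], strains[1])
    mid = 2
    left = _default_tree(strains[:mid])
    right = _default_tree(strains[mid:])
    return (left, right)


def expected_pairwise_divergence(
    tree: tuple | str, rate: float, strains: Sequence[str]
) -> pd.DataFrame:
    """Expected raw divergence (%) between leaves under uniform substitution.

    Each branch mutates each site with probability ``rate`` (to a uniformly
    chosen different base). Along a path of branches with rates p_b the chance
    that a site ends identical is 1/4 + 3/4 * prod(1 - 4 p_b / 3); divergence
    is 100 times the complement. Root-to-leaf depth is uniform in the default
    balanced-ish tree only approximately; the computation below uses exact
    path branch counts.
    """

    def depths(node, acc) -> dict[str, int]:
        if isinstance(node, str):
            return {node: acc}
        out: dict[str, int] = {}
        for child in node:
            out.update(depths(child, acc + 1))
        return out

    def paths(node) -> dict[str, list]:
        # number of branches between each pair = depth_a + depth_b - 2*depth_lca
        return depths(node, 0)

    leaf_depth = paths(tree)

    def lca_depth(node, a, b, acc=0):
        if isinstance(node, str):
            return None
        for child in node:
            leaves = depths(child, 0)
            if a in leaves and b in leaves:
                return lca_depth(child, a, b, acc + 1)
        return acc

    ids = list(strains)
    out = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i >= j:
                continue
            k = leaf_depth[a] + leaf_depth[b] - 2 * lca_depth(tree, a, b)
            identical = 0.25 + 0.75 * (1.0 - 4.0 * rate / 3.0) ** k
            out[i, j] = out[j, i] = 100.0 * (1.0 - identical)
    return pd.DataFrame(out, index=ids, columns=ids)


def generate_genomes(
    config: PangenomeConfig,
) -> tuple[list[GenomeSequence], pd.DataFrame]:
    """Evolve nucleotide genomes along the default strain tree.

    Returns the genomes plus the matrix of *expected* raw pairwise divergences
    (percent), against which measured ``100 - ANI`` can be compared. Uses an
    independent RNG stream (seed + 1) so proteome and genome output do not
    perturb each other's draws.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(config.seed + 1)
    tree = _default_tree(list(config.strains))
    root = "".join(rng.choice(NT, size=config.genome_length))

    genomes: dict[str, GenomeSequence] = {}

    def evolve(node, seq: str) -> None:
        if isinstance(node, str):
            genomes[node] = GenomeSequence(strain_id=node, contigs=[seq])
            return
        for child in node:
            child_seq = mutate_sequence(seq, config.genome_branch_rate, rng, alphabet=NT)
            evolve(child, child_seq)

    evolve(tree, root)
    expected = expected_pairwise_divergence(
        tree, config.genome_branch_rate, config.strains
    )
    ordered = [genomes[s] for s in config.strains]
    return ordered, expected


def write_pangenome(
    proteomes: Sequence[StrainProteome],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit per-strain FASTA + annotation TSV and truth.json; returns paths."""
    from .io import write_annotation_tsv, write_proteome_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for prot in proteomes:
        fasta = out_dir / f"{prot.strain_id}.faa"
        tsv = out_dir / f"{prot.strain_id}.cog.tsv"
        write_proteome_fasta(prot, fasta)
        write_annotation_tsv(prot, tsv)
        paths[f"{prot.strain_id}.fasta"] = fasta
        paths[f"{prot.strain_id}.annotation"] = tsv
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
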