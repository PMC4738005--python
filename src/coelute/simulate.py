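"""Synthetic multi-species co-fractionation worlds with known complexes.

The generator emulates the experimental design the pipeline targets:
several species, each profiled in several fractionation experiments, with a
shared set of ground-truth complexes defined in a reference gene namespace.
Per experiment, every complex elutes as one Gaussian peak — members share
the apex fraction and peak width, so their noise-free profiles are exactly
proportional — while monomeric proteins draw independent apexes. Apexes are
resampled per experiment, mimicking different fractionation techniques.

The noise model follows the two quantitation channels: MS2 spectral counts
are Poisson draws around ``ms2_depth x expected``, MS1 intensities multiply
the expected profile by per-cell log-normal noise. Whole-protein dropout
zeroes a profile with a small probability per experiment, emulating failed
detection. Each species conserves each reference gene with probability
``ortholog_conservation_prob`` (optionally duplicating it into 1-to-2
co-orthologs), which yields the ortholog maps the harmonization stage
consumes. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Optional

import numpy as np

from .learn import GoldStandard, load_gold_standard, write_gold_standard
from .orthology import OrthologMap, load_ortholog_map, write_ortholog_map
from .profiles import ContractError, ProfileMatrix, QuantKind, read_profile_matrix, write_profile_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "Experiment",
    "SyntheticWorld",
    "generate_world",
    "write_world",
    "read_world",
    "read_manifest",
]

# Gaussian peaks are truncated beyond this many widths from the apex so that
# profiles have realistic finite support instead of dense analytic tails.
_PEAK_SUPPORT_SIGMA = 4.0


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters of a synthetic fractionation world.

    Defaults describe a desk-scale world: 2 species, 20 complexes of 3-6
    members plus 40 monomers, 2 experiments per species, 60 fractions each.
    ``abundance_mu``/``abundance_sigma`` parameterize the log-normal peak
    amplitude (log-space mean 3.0 puts the median peak at ~20 spectral
    counts); ``peak_width_range`` is the chromatographic peak sigma in
    fraction units.
    """

    n_species: int = 2
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (3, 6)
    n_monomers: int = 40
    n_experiments_per_species: int = 2
    n_fractions: int = 60
    peak_width_range: tuple[float, float] = (1.0, 3.0)
    abundance_mu: float = 3.0
    abundance_sigma: float = 1.0
    ms2_depth: float = 1.0
    ms1_noise_cv: float = 0.2
    dropout_prob: float = 0.1
    ortholog_conservation_prob: float = 0.9
    duplication_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "ortholog_conservation_prob", "duplication_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractError(f"{name} must lie in [0, 1]")
        if self.n_fractions < 10:
            raise ContractError("n_fractions must be >= 10")
        for name in ("n_species", "n_complexes", "n_monomers", "n_experiments_per_species"):
            if getattr(self, name) < 1 and name != "n_monomers":
                raise ContractError(f"{name} must be positive")
        if self.n_monomers < 0:
            raise ContractError("n_monomers must be >= 0")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ContractError("complex_size_range must satisfy 2 <= lo <= hi")
        wlo, whi = self.peak_width_range
        if wlo <= 0 or whi < wlo:
            raise ContractError("peak_width_range must satisfy 0 < lo <= hi")
        if self.ms2_depth <= 0:
            raise ContractError("ms2_depth must be positive")
        if self.ms1_noise_cv < 0:
            raise ContractError("ms1_noise_cv must be >= 0")


@dataclass(frozen=True)
class Experiment:
    """One simulated fractionation run: MS2 + MS1 matrices plus the
    noise-free expected profiles (pre-dropout) they were drawn from."""

    experiment_id: str
    species: str
    ms2: ProfileMatrix
    ms1: ProfileMatrix
    expected: Optional[np.ndarray] = None  # rows align with ms2.protein_ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        same = (
            self.experiment_id == other.experiment_id
            and self.species == other.species
            and self.ms2 == other.ms2
            and self.ms1 == other.ms1
        )
        if not same:
            return False
        if self.expected is None or other.expected is None:
            return True  # expected profiles are in-memory extras, not files
        return np.array_equal(self.expected, other.expected)


@dataclass(frozen=True)
class SyntheticWorld:
    params: SimParams
    reference_genes: tuple[str, ...]
    species_genes: dict[str, tuple[str, ...]]
    ortholog_maps: dict[str, OrthologMap]
    complexes: GoldStandard
    experiments: tuple[Experiment, ...]
    positive_pairs: frozenset[tuple[str, str]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticWorld):
            return NotImplemented
        return (
            self.params == other.params
            and self.reference_genes == other.reference_genes
            and self.species_genes == other.species_genes
            and self.ortholog_maps == other.ortholog_maps
            and self.complexes == other.complexes
            and self.experiments == other.experiments
            and self.positive_pairs == other.positive_pairs
        )


def _gaussian_peak(n_fractions: int, apex: float, width: float) -> np.ndarray:
    """Unit-amplitude Gaussian elution peak truncated beyond 4 widths."""
    f = np.arange(n_fractions, dtype=float)
    shape = np.exp(-0.5 * ((f - apex) / width) ** 2)
    shape[np.abs(f - apex) > _PEAK_SUPPORT_SIGMA * width] = 0.0
    return shape


def generate_world(params: SimParams) -> SyntheticWorld:
    """Generate a complete synthetic world from one seed.

    The reference proteome is the union of complex members and monomers;
    species proteomes subsample it by the conservation probability (every
    complex member is guaranteed to survive in at least one species so the
    gold standard stays realizable). Per experiment, each complex draws an
    apex uniform over fractions and a width uniform over
    ``peak_width_range``; each protein draws a log-normal amplitude; the
    expected profile is amplitude x unit-amplitude Gaussian peak. MS2 counts
    are ``Poisson(ms2_depth x expected)``; MS1 is ``expected x
    LogNormal(0, ms1_noise_cv)``; dropout zeroes whole profiles.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_complexes)
    total_members = int(sizes.sum())
    n_genes = total_members + params.n_monomers
    if total_members > n_genes:
        raise ContractError("complex membership exceeds proteome size")
    width = len(str(n_genes))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(n_genes))
    complexes: list[tuple[str, frozenset[str]]] = []
    cursor = 0
    for c, size in enumerate(sizes):
        members = frozenset(genes[cursor : cursor + int(size)])
        complexes.append((f"cpx{c + 1:03d}", members))
        cursor += int(size)
    member_genes = genes[:total_members]
    gold = GoldStandard(tuple(complexes))
    complex_of: dict[str, int] = {}
    for idx, (_, members) in enumerate(complexes):
        for g in members:
            complex_of[g] = idx

    species_list = tuple(f"sp{i + 1}" for i in range(params.n_species))
    # conservation sampling: species s keeps gene g with the stated probability
    kept = rng.random((params.n_species, n_genes)) < params.ortholog_conservation_prob
    for gi, g in enumerate(member_genes):
        if not kept[:, gi].any():
            kept[rng.integers(params.n_species), gi] = True
    duplicated = np.zeros((params.n_species, n_genes), dtype=bool)
    if params.duplication_prob > 0:
        duplicated = kept & (rng.random((params.n_species, n_genes)) < params.duplication_prob)

    species_genes: dict[str, tuple[str, ...]] = {}
    ortholog_maps: dict[str, OrthologMap] = {}
    source_ref: dict[str, str] = {}  # species gene -> reference gene
    for si, sp in enumerate(species_list):
        sp_genes: list[str] = []
        entries: set[tuple[str, str]] = set()
        for gi, g in enumerate(genes):
            if not kept[si, gi]:
                continue
            name = f"{sp}_{g}"
            sp_genes.append(name)
            entries.add((name, g))
            source_ref[name] = g
            if duplicated[si, gi]:
                dup = f"{sp}_{g}b"
                sp_genes.append(dup)
                entries.add((dup, g))
                source_ref[dup] = g
        species_genes[sp] = tuple(sorted(sp_genes))
        ortholog_maps[sp] = OrthologMap(species=sp, entries=frozenset(entries))

    experiments: list[Experiment] = []
    n_frac = params.n_fractions
    for sp in species_list:
        ids = species_genes[sp]
        for e in range(params.n_experiments_per_species):
            exp_id = f"{sp}_e{e + 1}"
            cpx_apex = rng.uniform(0, n_frac - 1, size=params.n_complexes)
            cpx_width = rng.uniform(*params.peak_width_range, size=params.n_complexes)
            expected = np.zeros((len(ids), n_frac))
            for pi, sp_gene in enumerate(ids):
                ref = source_ref[sp_gene]
                amplitude = rng.lognormal(params.abundance_mu, params.abundance_sigma)
                if ref in complex_of:
                    ci = complex_of[ref]
                    apex, w = cpx_apex[ci], cpx_width[ci]
                else:
                    apex = rng.uniform(0, n_frac - 1)
                    w = rng.uniform(*params.peak_width_range)
                expected[pi] = amplitude * _gaussian_peak(n_frac, apex, w)
            dropout = rng.random(len(ids)) < params.dropout_prob
            observed = expected.copy()
            observed[dropout] = 0.0
            ms2_values = rng.poisson(params.ms2_depth * observed).astype(float)
            ms1_noise = rng.lognormal(0.0, params.ms1_noise_cv, size=observed.shape)
            ms1_values = observed * ms1_noise
            experiments.append(
                Experiment(
                    experiment_id=exp_id,
                    species=sp,
                    ms2=ProfileMatrix(exp_id, sp, QuantKind.MS2_COUNTS, ids, ms2_values),
                    ms1=ProfileMatrix(exp_id, sp, QuantKind.MS1_INTENSITY, ids, ms1_values),
                    expected=expected,
                )
            )
    world = SyntheticWorld(
        params=params,
        reference_genes=genes,
        species_genes=species_genes,
        ortholog_maps=ortholog_maps,
        complexes=gold,
        experiments=tuple(experiments),
        positive_pairs=gold.positive_pairs(),
    )
    logger.info(
        "generate_world(seed=%d): %d reference genes, %d complexes, %d experiments",
        params.seed, n_genes, params.n_complexes, len(experiments),
    )
    return world


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _params_to_manifest(params: SimParams) -> str:
    lines = []
    for f in dataclass_fields(params):
        v = getattr(params, f.name)
        if isinstance(v, tuple):
            v = ",".join(repr(x) for x in v)
        lines.append(f"{f.name}={v}")
    return "\n".join(lines) + "\n"


def read_manifest(path) -> SimParams:
    """Parse a manifest back into SimParams (sufficient to regenerate)."""
    raw: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or "=" not in ln:
                continue
            key, value = ln.split("=", 1)
            raw[key] = value
    kwargs: dict = {}
    for f in dataclass_fields(SimParams):
        if f.name not in raw:
            continue
        text = raw[f.name]
        if f.name == "complex_size_range":
            lo, hi = text.split(",")
            kwargs[f.name] = (int(lo), int(hi))
        elif f.name == "peak_width_range":
            lo, hi = text.split(",")
            kwargs[f.name] = (float(lo), float(hi))
        elif f.name in ("abundance_mu", "abundance_sigma", "ms2_depth", "ms1_noise_cv",
                        "dropout_prob", "ortholog_conservation_prob", "duplication_prob"):
            kwargs[f.name] = float(text)
        else:
            kwargs[f.name] = int(text)
    return SimParams(**kwargs)


def write_world(world: SyntheticWorld, directory) -> list[Path]:
    """Write all world files: per-experiment MS2/MS1 profile TSVs, per-species
    ortholog TSVs, the gold-standard complex file, and a manifest from which
    the identical world can be regenerated."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    manifest = directory / "manifest.txt"
    manifest.write_text(_params_to_manifest(world.params), encoding="utf-8")
    written.append(manifest)

    gold_path = directory / "gold_standard.tsv"
    write_gold_standard(world.complexes, gold_path)
    written.append(gold_path)

    ref_path = directory / "reference_genes.txt"
    ref_path.write_text("\n".join(world.reference_genes) + "\n", encoding="utf-8")
    written.append(ref_path)

    for sp, omap in sorted(world.ortholog_maps.items()):
        path = directory / f"orthologs_{sp}.tsv"
        write_ortholog_map(omap, path)
        written.append(path)

    for exp in world.experiments:
        ms2_path = directory / f"{exp.experiment_id}_ms2.tsv"
        ms1_path = directory / f"{exp.experiment_id}_ms1.tsv"
        write_profile_matrix(exp.ms2, ms2_path)
        write_profile_matrix(exp.ms1, ms1_path)
        written.extend([ms2_path, ms1_path])
    return written


def read_world(directory) -> SyntheticWorld:
    """Load a written world back; expected profiles are regenerated from the
    manifest so read-back compares equal to the in-memory original."""
    directory = Path(directory)
    params = read_manifest(directory / "manifest.txt")
    gold = load_gold_standard(directory / "gold_standard.tsv")
    species_list = tuple(f"sp{i + 1}" for i in range(params.n_species))
    ortholog_maps = {
        sp: load_ortholog_map(directory / f"orthologs_{sp}.tsv", sp) for sp in species_list
    }
    species_genes = {
        sp: tuple(sorted({src for src, _ in ortholog_maps[sp].entries}))
        for sp in species_list
    }
    experiments: list[Experiment] = []
    for sp in species_list:
        for e in range(params.n_experiments_per_species):
            exp_id = f"{sp}_e{e + 1}"
            ms2 = read_profile_matrix(
                directory / f"{exp_id}_ms2.tsv", QuantKind.MS2_COUNTS, exp_id, sp
            )
            ms1 = read_profile_matrix(
                directory / f"{exp_id}_ms1.tsv", QuantKind.MS1_INTENSITY, exp_id, sp
            )
            experiments.append(Experiment(exp_id, sp, ms2, ms1, expected=None))
    ref_path = directory / "reference_genes.txt"
    reference_genes = tuple(
        ln for ln in ref_path.read_text(encoding="utf-8").splitlines() if ln
    )
    return SyntheticWorld(
        params=params,
        reference_genes=reference_genes,
        species_genes=species_genes,
        ortholog_maps=ortholog_maps,
        complexes=gold,
        experiments=tuple(experiments),
        positive_pairs=gold.positive_pairs(),
    )
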