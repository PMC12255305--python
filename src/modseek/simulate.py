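"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions of the discovery workflow:
a five-genome comparative panel (two trait-positive, three negative)
with one planted candidate family; a 76-nt tRNA-like transcript whose
acceptor-stem prefix reads G,G,G,G,G,C,G,U and whose 3' end is A-C-C-A
(an explicitly synthetic stand-in — the full natural sequence is not
reproduced); peak lists of digestion fragment ions with ppm-scale
Gaussian noise and uniform decoys; and kinetic series on the assay's
concentration/time grids with multiplicative Gaussian noise, three
replicates by default.

Every generator is a pure function of its config (seed included):
identical configs yield identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .alignment import ProteinRecord, Proteome
from .digestion import DigestOptions, EnzymeSpec, RNASE_A, digest
from .kinetics import SaturationSeries, TimeCourse
from .masscalc import PeakList, fragment_mass, mz_negative, PROTON_MASS
from .rna import (
    ModifiedRnaSequence,
    Residue,
    RnaValidationError,
    TrnaAnnotation,
    mutate_pair,
)
from .screen import GenomeLabel, NEGATIVE, POSITIVE

__all__ = [
    "ScreenFixtureConfig",
    "ScreenFixture",
    "SpectrumFixtureConfig",
    "PeakListFixture",
    "KineticsFixtureConfig",
    "make_screen_fixture",
    "make_wt_trna",
    "make_trna_panel",
    "PanelEntry",
    "make_peaklist",
    "make_kinetic_series",
    "EXPONENTIAL_TIME_GRID_MIN",
    "TRNA_CONC_GRID_UM",
    "SAM_CONC_GRID_UM",
    "INHIBITOR_CONC_GRID_UM",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# assay grids used throughout the characterization experiments
EXPONENTIAL_TIME_GRID_MIN = (0.0, 1.0, 3.0, 5.0, 10.0, 20.0, 30.0, 40.0)
TRNA_CONC_GRID_UM = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
SAM_CONC_GRID_UM = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
INHIBITOR_CONC_GRID_UM = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
GROWTH_TIME_GRID_H = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


# ---------------------------------------------------------------------------
# Comparative-genomics fixture


@dataclass(frozen=True)
class ScreenFixtureConfig:
    """Synthetic genome panel with a planted candidate family.

    Defaults emulate the discovery panel: 2 trait-positive genomes
    (reference included), 3 negative genomes, 60 genes per genome.
    Genes are 80-160 aa; homolog copies diverge by independent per-site
    substitution.
    """

    seed: int
    n_positive_genomes: int = 2
    n_negative_genomes: int = 3
    genes_per_genome: int = 60
    planted_family_size: int = 1
    per_site_substitution_prob: float = 0.1
    housekeeping_fraction: float = 0.2
    min_gene_length: int = 80
    max_gene_length: int = 160

    def __post_init__(self) -> None:
        if self.n_positive_genomes < 1:
            raise ValueError("at least one positive genome (the reference) is required")
        if not 0.0 <= self.per_site_substitution_prob <= 1.0:
            raise ValueError("per_site_substitution_prob must be in [0, 1]")
        if not 0.0 <= self.housekeeping_fraction <= 1.0:
            raise ValueError("housekeeping_fraction must be in [0, 1]")
        n_hk = int(round(self.housekeeping_fraction * self.genes_per_genome))
        if self.planted_family_size + n_hk > self.genes_per_genome:
            raise ValueError("planted family plus housekeeping exceed genes_per_genome")


@dataclass(frozen=True)
class ScreenFixture:
    reference: Proteome
    others: tuple[tuple[GenomeLabel, Proteome], ...]
    planted_gene_ids: tuple[str, ...]


_PLANTED_ANNOTATION = "putative tRNA (guanine) methyltransferase"
_HK_ANNOTATIONS = (
    "DNA polymerase subunit",
    "ribosomal protein L2",
    "elongation factor Tu",
    "ATP synthase beta subunit",
    "chaperonin GroEL",
    "DNA gyrase subunit A",
)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, p: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < p:
            choices = AMINO_ACIDS.replace(aa, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def make_screen_fixture(config: ScreenFixtureConfig) -> ScreenFixture:
    """Generate the labeled genome panel.

    Planted family members appear (as mutated copies) in every positive
    genome and in no negative genome; housekeeping families appear in
    all genomes; the remaining genes are genome-private random
    sequences.
    """
    rng = np.random.default_rng(config.seed)
    n_hk = int(round(config.housekeeping_fraction * config.genes_per_genome))
    n_planted = config.planted_family_size
    n_private = config.genes_per_genome - n_hk - n_planted

    def gene_length() -> int:
        return int(rng.integers(config.min_gene_length, config.max_gene_length + 1))

    planted_master = [_random_protein(rng, gene_length()) for _ in range(n_planted)]
    hk_master = [_random_protein(rng, gene_length()) for _ in range(n_hk)]

    def build_genome(gid: str, planted: bool, private_count: int) -> Proteome:
        records = []
        if planted:
            for i, master in enumerate(planted_master, start=1):
                seq = (
                    master
                    if gid == "REF"
                    else _mutate_protein(rng, master, config.per_site_substitution_prob)
                )
                records.append(
                    ProteinRecord(f"{gid}_cand{i:02d}", seq, _PLANTED_ANNOTATION)
                )
        for i, master in enumerate(hk_master, start=1):
            seq = (
                master
                if gid == "REF"
                else _mutate_protein(rng, master, config.per_site_substitution_prob)
            )
            ann = _HK_ANNOTATIONS[(i - 1) % len(_HK_ANNOTATIONS)]
            records.append(ProteinRecord(f"{gid}_hk{i:02d}", seq, ann))
        for i in range(1, private_count + 1):
            records.append(
                ProteinRecord(
                    f"{gid}_priv{i:03d}",
                    _random_protein(rng, gene_length()),
                    "hypothetical protein",
                )
            )
        return Proteome(gid, tuple(records))

    reference = build_genome("REF", planted=True, private_count=n_private)
    others = []
    for k in range(2, config.n_positive_genomes + 1):
        gid = f"POS{k}"
        others.append(
            (GenomeLabel(gid, POSITIVE), build_genome(gid, True, n_private))
        )
    for k in range(1, config.n_negative_genomes + 1):
        gid = f"NEG{k}"
        others.append(
            (
                GenomeLabel(gid, NEGATIVE),
                build_genome(gid, False, n_private + n_planted),
            )
        )
    planted_ids = tuple(f"REF_cand{i:02d}" for i in range(1, n_planted + 1))
    return ScreenFixture(reference, tuple(others), planted_ids)


# ---------------------------------------------------------------------------
# tRNA constructs

# 76-nt synthetic tRNA-like scaffold.  Acceptor stem: positions 1-7
# (GGGGGCG) paired with 66-72 (CGCCCCC), position 6 = C pairing G67;
# position 8 = U; D-arm 10-25; anticodon arm 26-44; variable loop 45-48;
# T-arm 49-65; discriminator A73; CCA 74-76.
_WT_SEGMENTS = {
    "acceptor5": (1, 7, "GGGGGCG"),
    "pos8": (8, 9, "UA"),
    "D": (10, 25, "GCGGCAGUUGGUAGAG"),
    "anticodon": (26, 44, "CUCAGGCUCCAAAUCCUGA"),
    "variable": (45, 48, "AGGU"),
    "T": (49, 65, "CGUGGGUUCGAAUCCCA"),
    "acceptor3": (66, 72, "CGCCCCC"),
    "ncca": (73, 76, "ACCA"),
}

_WT_SEQUENCE = "".join(seg for _, _, seg in _WT_SEGMENTS.values())
assert len(_WT_SEQUENCE) == 76

_ARM_RANGES = {"D": (10, 25), "anticodon": (26, 44), "T": (49, 65)}


def make_wt_trna(
    cm6: bool = False, name: str | None = None
) -> tuple[ModifiedRnaSequence, TrnaAnnotation]:
    """The synthetic wild-type tRNA transcript, optionally Cm6-modified."""
    residues = [Residue(b) for b in _WT_SEQUENCE]
    if cm6:
        residues[5] = Residue("C", "Cm")
    seq = ModifiedRnaSequence(
        name or ("tRNA-WT-Cm6" if cm6 else "tRNA-WT"), tuple(residues)
    )
    ann = TrnaAnnotation(
        {i: i for i in range(1, 77)},
        frozenset({"acceptor", "D", "anticodon", "T"}),
        has_discriminator=True,
    )
    return seq, ann


def _delete_positions(
    seq: ModifiedRnaSequence,
    ann: TrnaAnnotation,
    ranges: Sequence[tuple[int, int]],
    name: str,
    arms_removed: frozenset[str] = frozenset(),
    discriminator_removed: bool = False,
) -> tuple[ModifiedRnaSequence, TrnaAnnotation]:
    drop = set()
    for lo, hi in ranges:
        drop.update(range(lo, hi + 1))
    kept = [
        (idx, res)
        for idx, res in enumerate(seq.residues, start=1)
        if ann.canonical_position_map[idx] not in drop
    ]
    residues = tuple(res for _, res in kept)
    posmap = {
        new_idx: ann.canonical_position_map[old_idx]
        for new_idx, (old_idx, _) in enumerate(kept, start=1)
    }
    new_ann = TrnaAnnotation(
        posmap,
        ann.arms_present - arms_removed,
        has_discriminator=ann.has_discriminator and not discriminator_removed,
    )
    return replace(seq, name=name, residues=residues), new_ann


@dataclass(frozen=True)
class PanelEntry:
    name: str
    sequence: ModifiedRnaSequence
    annotation: TrnaAnnotation
    expected_substrate: bool


def make_trna_panel() -> list[PanelEntry]:
    """The twelve-construct mutant/truncation panel with truth labels.

    Wild type, the three acceptor-pair 6-67 swaps, six arm truncations,
    the ACCA deletion, and the acceptor-stem micro-helix.
    """
    wt, ann = make_wt_trna()
    entries = [PanelEntry("WT", wt, ann, True)]
    for pair, verdict in [("AU", True), ("UA", True), ("GC", False)]:
        mut = mutate_pair(wt, ann, 6, pair)
        mut = replace(mut, name=f"{pair[0]}6-{pair[1]}67")
        entries.append(PanelEntry(mut.name, mut, ann, verdict))

    arm_sets = [
        ("dD", ("D",)),
        ("dAC", ("anticodon",)),
        ("dT", ("T",)),
        ("dAC+dT", ("anticodon", "T")),
        ("dD+dT", ("D", "T")),
        ("dD+dAC", ("D", "anticodon")),
    ]
    for label, arms in arm_sets:
        seq, a = _delete_positions(
            wt,
            ann,
            [_ARM_RANGES[arm] for arm in arms],
            name=label,
            arms_removed=frozenset(arms),
        )
        entries.append(PanelEntry(label, seq, a, True))

    no_acca, a = _delete_positions(
        wt, ann, [(73, 76)], name="-ACCA", discriminator_removed=True
    )
    entries.append(PanelEntry("-ACCA", no_acca, a, False))

    # micro-helix: acceptor stem closed by a tetraloop, CCA retained
    micro, a = _delete_positions(
        wt,
        ann,
        [(10, 25), (26, 44), (45, 48), (49, 65)],
        name="micro-helix",
        arms_removed=frozenset({"D", "anticodon", "T"}),
    )
    entries.append(PanelEntry("micro-helix", micro, a, False))
    return entries


# ---------------------------------------------------------------------------
# Peak-list fixture


@dataclass(frozen=True)
class SpectrumFixtureConfig:
    """Digestion peak list with planted ribose methylations and decoys."""

    seed: int
    planted_ribose_methyl_positions: tuple[int, ...] = (6,)
    enzyme: EnzymeSpec = RNASE_A
    phosphatase: bool = True
    charges: tuple[int, ...] = (1, 2, 3, 4, 5)
    ppm_noise_sigma: float = 0.0
    n_decoys: int = 20
    decoy_min_ppm_distance: float = 50.0
    scan_window: tuple[float, float] = (600.0, 2000.0)


@dataclass(frozen=True)
class PeakListFixture:
    peaks: PeakList
    parent: ModifiedRnaSequence
    truth: tuple[tuple[int, int, int, float], ...]  # (start, end, charge, true m/z)
    n_decoys: int


_RIBOSE_CODE = {"A": "Am", "C": "Cm", "G": "Gm", "U": "Um"}


def make_peaklist(config: SpectrumFixtureConfig) -> PeakListFixture:
    """Peak list of the digestion fragment ions of a modified transcript.

    True peaks sit at the theoretical [M - zH]z- m/z of every digest
    fragment ion inside the scan window, perturbed by Gaussian ppm
    noise; decoys are uniform in the window, placed at least
    ``decoy_min_ppm_distance`` ppm from any true ion.
    """
    rng = np.random.default_rng(config.seed)
    wt, _ = make_wt_trna()
    residues = list(wt.residues)
    for pos in config.planted_ribose_methyl_positions:
        base = residues[pos - 1].base
        residues[pos - 1] = Residue(base, _RIBOSE_CODE[base])
    parent = ModifiedRnaSequence("synthetic-modified", tuple(residues))

    frags = digest(parent, config.enzyme, DigestOptions(phosphatase=config.phosphatase))
    lo, hi = config.scan_window
    truth = []
    mzs, intens = [], []
    for f in frags:
        mass = fragment_mass(f)
        for z in config.charges:
            if mass <= z * PROTON_MASS:
                continue
            mz = mz_negative(mass, z)
            if not lo <= mz <= hi:
                continue
            observed = mz * (1.0 + rng.normal(0.0, config.ppm_noise_sigma) * 1e-6)
            observed = min(max(observed, lo), hi)
            truth.append((f.start, f.end, z, mz))
            mzs.append(observed)
            intens.append(float(rng.uniform(1e4, 1e6)))

    true_mz = np.array([t[3] for t in truth])
    n_placed = 0
    while n_placed < config.n_decoys:
        cand = rng.uniform(lo, hi)
        if len(true_mz) and np.min(np.abs(cand - true_mz) / true_mz) * 1e6 < config.decoy_min_ppm_distance:
            continue
        mzs.append(cand)
        intens.append(float(rng.uniform(1e3, 1e5)))
        n_placed += 1

    peaks = PeakList(
        np.array(mzs), np.array(intens), scan_window=config.scan_window
    )
    return PeakListFixture(peaks, parent, tuple(truth), config.n_decoys)


# ---------------------------------------------------------------------------
# Kinetics fixtures


#: plausible truth values per model (progress-curve plateau/rate; the
#: assay-scale Km; a mid-grid IC50; a thermophile-scale doubling time)
DEFAULT_TRUE_PARAMETERS = {
    "single_exponential": {"A": 1000.0, "B": -1000.0, "k_obs": 0.1},
    "michaelis_menten": {"Km": 8.2, "Vmax": 1.0},
    "ic50": {"IC50": 30.0},
    "growth": {"doubling_time_h": 2.19, "OD0": 0.02},
}


@dataclass(frozen=True)
class KineticsFixtureConfig:
    """Replicated kinetic series from a known model.

    y = model(x; truth) * (1 + eps), eps ~ N(0, sigma), independent
    across points and replicates.  Default grids are the assay's stated
    time/concentration series; three replicates.
    """

    seed: int
    model: str = "single_exponential"  # | michaelis_menten | ic50 | growth
    true_parameters: dict | None = None
    x_grid: tuple[float, ...] | None = None
    relative_noise_sigma: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.model not in DEFAULT_TRUE_PARAMETERS:
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if self.true_parameters is None:
            object.__setattr__(
                self, "true_parameters", dict(DEFAULT_TRUE_PARAMETERS[self.model])
            )

    def grid(self) -> tuple[float, ...]:
        if self.x_grid is not None:
            return self.x_grid
        return {
            "single_exponential": EXPONENTIAL_TIME_GRID_MIN,
            "michaelis_menten": TRNA_CONC_GRID_UM,
            "ic50": INHIBITOR_CONC_GRID_UM,
            "growth": GROWTH_TIME_GRID_H,
        }[self.model]


def _model_values(model: str, params: dict, x: np.ndarray) -> np.ndarray:
    if model == "single_exponential":
        return params["A"] + params["B"] * np.exp(-params["k_obs"] * x)
    if model == "michaelis_menten":
        return params["Vmax"] * x / (params["Km"] + x)
    if model == "ic50":
        return 1.0 / (1.0 + x / params["IC50"])
    if model == "growth":
        od0 = params.get("OD0", 0.02)
        return od0 * np.exp(np.log(2.0) / params["doubling_time_h"] * x)
    raise RnaValidationError(f"unknown kinetic model {model!r}")


def make_kinetic_series(config: KineticsFixtureConfig) -> list:
    """Replicated series with truth parameters; the return type follows
    the model: TimeCourse for progress curves and growth, SaturationSeries
    for Michaelis-Menten, (conc, activity) arrays for IC50."""
    rng = np.random.default_rng(config.seed)
    x = np.array(config.grid(), dtype=float)
    out = []
    for _ in range(config.n_replicates):
        y = _model_values(config.model, config.true_parameters, x)
        y = y * (1.0 + rng.normal(0.0, config.relative_noise_sigma, size=x.shape))
        if config.model in ("single_exponential",):
            out.append(TimeCourse(x, y, time_unit="min"))
        elif config.model == "growth":
            out.append(TimeCourse(x, y, time_unit="h"))
        elif config.model == "michaelis_menten":
            out.append(SaturationSeries(x, y))
        else:
            out.append((x.copy(), y))
    return out
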