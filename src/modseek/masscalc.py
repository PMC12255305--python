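"""Elemental composition, monoisotopic mass and negative-mode m/z of
(modified) RNA fragments; peak matching; ribose-methyl localization;
nucleoside-level relative quantification.

Mass arithmetic is purely additive: each residue contributes its
nucleoside formula (plus any modification delta), each internucleotide
linkage adds HPO3 and removes H2O, terminal phosphates add HPO3 (a
2',3'-cyclic phosphate is the linear one minus H2O), and a deprotonated
ion [M - zH]z- has m/z = (M - z * 1.0072765) / z.  Every methyl
modification (2'-O or C5) shifts the monoisotopic mass by exactly
+14.015650 Da; only the 2'-O placement blocks ribonuclease cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

from .digestion import Fragment
from .modifications import MODIFICATIONS
from .rna import ModifiedRnaSequence, Residue, RnaValidationError

__all__ = [
    "ElementalFormula",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "NUCLEOSIDE_FORMULAS",
    "METHYL_DELTA_DA",
    "PeakList",
    "TheoreticalIon",
    "FragmentMatch",
    "LocalizationCall",
    "fragment_formula",
    "monoisotopic_mass",
    "average_mass",
    "fragment_mass",
    "mz_negative",
    "theoretical_ions",
    "match_peaks",
    "localize_ribose_methyl",
    "relative_mod_level",
    "read_peaklist",
    "write_peaklist",
]

ELEMENTS = ("C", "H", "N", "O", "P")

#: monoisotopic atomic masses [Da]
MONOISOTOPIC_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: standard atomic weights for average-mass reporting [Da]
AVERAGE_MASS = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
}

#: mass removed per deprotonation [Da]
PROTON_MASS = 1.0072765

#: CH2, the shift of any single methylation
METHYL_DELTA_DA = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"]


@dataclass(frozen=True)
class ElementalFormula:
    """Nonnegative element counts over C, H, N, O, P with component-wise
    addition and subtraction."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise RnaValidationError(f"negative {el} count in formula {self}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            **{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS}
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            **{el: getattr(self, el) - getattr(other, el) for el in ELEMENTS}
        )

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula(**{el: getattr(self, el) * k for el in ELEMENTS})

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS if getattr(self, el)}

    def hill(self) -> str:
        return "".join(
            f"{el}{getattr(self, el)}" for el in ELEMENTS if getattr(self, el)
        )


#: free ribonucleoside compositions
NUCLEOSIDE_FORMULAS = {
    "A": ElementalFormula(C=10, H=13, N=5, O=4),
    "C": ElementalFormula(C=9, H=13, N=3, O=5),
    "G": ElementalFormula(C=10, H=13, N=5, O=5),
    "U": ElementalFormula(C=9, H=12, N=2, O=6),
}

HPO3 = ElementalFormula(H=1, O=3, P=1)
H2O = ElementalFormula(H=2, O=1)


def _residue_formula(res: Residue) -> ElementalFormula:
    f = NUCLEOSIDE_FORMULAS[res.base]
    if res.mod_code:
        entry = MODIFICATIONS.get(res.mod_code)
        if entry is None:
            raise RnaValidationError(f"unknown modification code {res.mod_code!r}")
        f = f + ElementalFormula(**entry.delta_formula)
    return f


def fragment_formula(fragment: Fragment | ModifiedRnaSequence) -> ElementalFormula:
    """Elemental composition of an oligonucleotide (fragment or whole RNA).

    Sum of nucleoside formulas and modification deltas, plus HPO3 - H2O
    per internucleotide linkage, plus terminal chemistry: a 3' linear
    phosphate or 5' monophosphate adds HPO3, a 2',3'-cyclic phosphate
    adds HPO3 - H2O, and a 5'-triphosphate adds 3 x HPO3.
    """
    residues = fragment.residues
    f = ElementalFormula()
    for res in residues:
        f = f + _residue_formula(res)
    n_waters = len(residues) - 1  # one condensation per linkage
    f = f + (len(residues) - 1) * HPO3
    if fragment.three_prime == "linear_phosphate":
        f = f + HPO3
    elif fragment.three_prime == "cyclic_phosphate":
        f = f + HPO3
        n_waters += 1
    if fragment.five_prime == "monophosphate":
        f = f + HPO3
    elif fragment.five_prime == "triphosphate":
        f = f + 3 * HPO3
    return f - n_waters * H2O


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da (linear in element counts)."""
    return sum(getattr(formula, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS)


def average_mass(formula: ElementalFormula) -> float:
    """Average (isotope-abundance-weighted) mass in Da.

    Provided for comparison with low-resolution data; all matching and
    reporting defaults to monoisotopic masses.
    """
    return sum(getattr(formula, el) * AVERAGE_MASS[el] for el in ELEMENTS)


def fragment_mass(fragment: Fragment | ModifiedRnaSequence) -> float:
    return monoisotopic_mass(fragment_formula(fragment))


def mz_negative(mass: float, z: int) -> float:
    """m/z of the deprotonated ion [M - zH]z-."""
    if z < 1:
        raise RnaValidationError("charge z must be a positive integer")
    mz = (mass - z * PROTON_MASS) / z
    if mz <= 0:
        raise RnaValidationError(f"nonpositive m/z for mass {mass} at charge {z}")
    return mz


# ---------------------------------------------------------------------------
# Peak lists and matching


@dataclass(frozen=True)
class PeakList:
    """Observed centroided peaks: ascending m/z with intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    scan_window: tuple[float, float] = (600.0, 2000.0)
    charge: np.ndarray | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise RnaValidationError("mz and intensity must have equal length")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        charge = self.charge
        if charge is not None:
            charge = np.asarray(charge)[order]
        lo, hi = self.scan_window
        if len(mz) and (mz[0] < lo or mz[-1] > hi):
            raise RnaValidationError("peak m/z outside the scan window")
        if (inten < 0).any():
            raise RnaValidationError("intensities must be nonnegative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "charge", charge)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class TheoreticalIon:
    fragment: Fragment
    charge: int
    mz: float


@dataclass(frozen=True)
class FragmentMatch:
    """Assignment of an observed peak to a theoretical fragment ion."""

    fragment: Fragment
    charge: int
    theoretical_mz: float
    observed_mz: float
    intensity: float
    error_da: float
    error_ppm: float


def theoretical_ions(
    fragments: Sequence[Fragment],
    charges: Iterable[int] = range(1, 6),
    scan_window: tuple[float, float] = (600.0, 2000.0),
) -> list[TheoreticalIon]:
    """All [M - zH]z- ions of the fragments whose m/z falls in the window."""
    lo, hi = scan_window
    ions = []
    for frag in fragments:
        mass = fragment_mass(frag)
        for z in charges:
            if mass <= z * PROTON_MASS:
                continue
            mz = mz_negative(mass, z)
            if lo <= mz <= hi:
                ions.append(TheoreticalIon(frag, z, mz))
    return ions


def match_peaks(
    peaks: PeakList,
    fragments: Sequence[Fragment],
    charges: Iterable[int] = range(1, 6),
    tolerance_ppm: float = 20.0,
    tolerance_da: float | None = None,
) -> list[FragmentMatch]:
    """Assign observed peaks to theoretical fragment ions.

    A peak matches an ion when their m/z difference is within the
    tolerance (ppm by default; ``tolerance_da`` switches to an absolute
    window).  Each observed peak is assigned to at most one fragment
    ion: smallest |ppm error| wins, ties broken by lower charge.  Ions
    outside the scan window are never considered.
    """
    ions = theoretical_ions(fragments, charges, peaks.scan_window)
    matches: list[FragmentMatch] = []
    for mz_obs, inten in zip(peaks.mz, peaks.intensity):
        best: tuple[float, int, TheoreticalIon] | None = None
        for ion in ions:
            err_da = mz_obs - ion.mz
            err_ppm = err_da / ion.mz * 1e6
            if tolerance_da is not None:
                ok = abs(err_da) <= tolerance_da
            else:
                ok = abs(err_ppm) <= tolerance_ppm
            if not ok:
                continue
            key = (abs(err_ppm), ion.charge)
            if best is None or key < (best[0], best[1]):
                best = (abs(err_ppm), ion.charge, ion)
        if best is not None:
            ion = best[2]
            matches.append(
                FragmentMatch(
                    fragment=ion.fragment,
                    charge=ion.charge,
                    theoretical_mz=ion.mz,
                    observed_mz=float(mz_obs),
                    intensity=float(inten),
                    error_da=float(mz_obs - ion.mz),
                    error_ppm=float((mz_obs - ion.mz) / ion.mz * 1e6),
                )
            )
    return matches


# ---------------------------------------------------------------------------
# Modification localization from paired digests


@dataclass(frozen=True)
class LocalizationCall:
    """A 2'-O-methyl call: exact parent position (blocking evidence) or a
    fragment range (mass-shift evidence, position within not resolved)."""

    position: int | None
    fragment_range: tuple[int, int]
    evidence: str  # "blocking" | "mass_shift"
    mass_delta: float


def localize_ribose_methyl(
    control_fragments: Sequence[Fragment],
    modified_fragments: Sequence[Fragment],
    control_masses: Sequence[float] | None = None,
    modified_masses: Sequence[float] | None = None,
    tolerance_da: float = 0.01,
) -> list[LocalizationCall]:
    """Locate 2'-O-methylations by comparing control and modified digests
    of the same parent.

    Blocking evidence: a fragment in the modified digest spans a run of
    k+1 adjacent control fragments, and its mass equals the merged
    control mass plus k methyls (+k x 14.0157 Da), where merging
    replaces each joined terminal-group pair by one internucleotide
    linkage; every blocked site — the 3' residue of each upstream
    control fragment in the run — is called exactly.  Mass-shift evidence: a control fragment reappears at the
    same coordinates shifted by +14.0157 Da; the methyl lies within the
    fragment but the exact residue is not resolved from mass alone.

    Masses default to theoretical fragment masses; pass observed
    (deconvoluted) masses to localize from measured data.
    """
    if control_masses is None:
        control_masses = [fragment_mass(f) for f in control_fragments]
    if modified_masses is None:
        modified_masses = [fragment_mass(f) for f in modified_fragments]
    parents = {f.parent_name for f in control_fragments} | {
        f.parent_name for f in modified_fragments
    }
    if len(parents) > 1:
        raise RnaValidationError(f"digests derive from different parents: {sorted(parents)}")

    control = sorted(
        zip(control_fragments, control_masses), key=lambda fm: fm[0].start
    )
    calls: list[LocalizationCall] = []

    by_coords = {(f.start, f.end): m for f, m in zip(modified_fragments, modified_masses)}
    ctrl_by_coords = {(f.start, f.end): m for f, m in control}

    def _term3_mass(frag: Fragment) -> float:
        if frag.three_prime == "linear_phosphate":
            return monoisotopic_mass(HPO3)
        if frag.three_prime == "cyclic_phosphate":
            return monoisotopic_mass(HPO3) - monoisotopic_mass(H2O)
        return 0.0

    def _term5_mass(frag: Fragment) -> float:
        if frag.five_prime == "monophosphate":
            return monoisotopic_mass(HPO3)
        if frag.five_prime == "triphosphate":
            return 3 * monoisotopic_mass(HPO3)
        return 0.0

    # blocking: a run of adjacent control fragments merged in the
    # modified digest; k joined junctions imply k blocked (methylated)
    # sites and a +k*CH2 shift over the condensation bookkeeping
    linkage = monoisotopic_mass(HPO3) - monoisotopic_mass(H2O)
    for i in range(len(control)):
        f_i, m_i = control[i]
        expected = m_i
        for j in range(i + 1, len(control)):
            f_prev = control[j - 1][0]
            f_j, m_j = control[j]
            if f_prev.end + 1 != f_j.start:
                break
            expected += m_j - _term3_mass(f_prev) - _term5_mass(f_j) + linkage
            merged = by_coords.get((f_i.start, f_j.end))
            if merged is None:
                continue
            k = j - i
            delta = merged - expected
            if abs(delta - k * METHYL_DELTA_DA) <= tolerance_da:
                for blocked in range(i, j):
                    calls.append(
                        LocalizationCall(
                            position=control[blocked][0].end,
                            fragment_range=(f_i.start, f_j.end),
                            evidence="blocking",
                            mass_delta=delta,
                        )
                    )

    # mass shift: same coordinates, +CH2
    for (start, end), m_mod in sorted(by_coords.items()):
        m_ctrl = ctrl_by_coords.get((start, end))
        if m_ctrl is None:
            continue
        delta = m_mod - m_ctrl
        if abs(delta - METHYL_DELTA_DA) <= tolerance_da:
            calls.append(
                LocalizationCall(
                    position=None,
                    fragment_range=(start, end),
                    evidence="mass_shift",
                    mass_delta=delta,
                )
            )
    calls.sort(key=lambda c: c.fragment_range)
    return calls


def relative_mod_level(
    sample_areas: Mapping[str, float],
    reference_areas: Mapping[str, float],
    analyte: str = "Cm",
    normalizer: str = "G",
) -> float:
    """Relative modification level in percent, reference = 100%.

    Both analyte signals are first normalized to the normalizer
    nucleoside (e.g. guanosine) within their own run, cancelling
    injection-amount differences; the sample ratio is then expressed
    relative to the reference ratio.
    """
    for name, areas in (("sample", sample_areas), ("reference", reference_areas)):
        if areas.get(normalizer, 0.0) <= 0:
            raise RnaValidationError(
                f"{name} normalizer {normalizer!r} area must be positive"
            )
    sample_ratio = sample_areas.get(analyte, 0.0) / sample_areas[normalizer]
    reference_ratio = reference_areas.get(analyte, 0.0) / reference_areas[normalizer]
    if reference_ratio <= 0:
        raise RnaValidationError(f"reference has no {analyte!r} signal")
    return 100.0 * sample_ratio / reference_ratio


# ---------------------------------------------------------------------------
# Peak-list files: tab-separated mz / intensity [/ charge] with a header


def write_peaklist(peaks: PeakList, dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_peaklist(peaks, fh)
        return
    has_charge = peaks.charge is not None
    dest.write(
        f"# polarity={peaks.polarity} scan_window={peaks.scan_window[0]:g},{peaks.scan_window[1]:g}\n"
    )
    dest.write("mz\tintensity\tcharge\n" if has_charge else "mz\tintensity\n")
    for i in range(len(peaks)):
        row = f"{peaks.mz[i]:.6f}\t{peaks.intensity[i]:.6g}"
        if has_charge:
            row += f"\t{int(peaks.charge[i])}"
        dest.write(row + "\n")


def read_peaklist(source: Union[str, Path, TextIO]) -> PeakList:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_peaklist(fh)
    polarity, window = "negative", (600.0, 2000.0)
    mz, inten, charge = [], [], []
    has_charge = False
    for line in source:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if token.startswith("polarity="):
                    polarity = token.split("=", 1)[1]
                elif token.startswith("scan_window="):
                    lo, hi = token.split("=", 1)[1].split(",")
                    window = (float(lo), float(hi))
            continue
        if line.startswith("mz"):
            has_charge = line.split("\t")[-1] == "charge"
            continue
        fields = line.split("\t")
        mz.append(float(fields[0]))
        inten.append(float(fields[1]))
        if has_charge:
            charge.append(int(fields[2]))
    # peaks outside the scan window cannot be instrument signal in that
    # window: drop them with a warning instead of failing
    keep = [i for i, m in enumerate(mz) if window[0] <= m <= window[1]]
    if len(keep) != len(mz):
        import warnings

        warnings.warn(
            f"dropped {len(mz) - len(keep)} peak(s) outside the scan window "
            f"{window[0]:g}-{window[1]:g}",
            stacklevel=2,
        )
        mz = [mz[i] for i in keep]
        inten = [inten[i] for i in keep]
        if has_charge:
            charge = [charge[i] for i in keep]
    return PeakList(
        np.array(mz),
        np.array(inten),
        polarity=polarity,
        scan_window=window,
        charge=np.array(charge) if has_charge else None,
    )


def fragment_ion_report(
    fragments: Sequence[Fragment],
    charges: Iterable[int] = range(1, 6),
    scan_window: tuple[float, float] = (600.0, 2000.0),
    matches: Sequence[FragmentMatch] = (),
) -> dict:
    """JSON-serializable report of fragments, formulas, masses, per-charge
    m/z within the scan window, and any peak assignments."""
    charges = list(charges)
    rows = []
    for frag in fragments:
        formula = fragment_formula(frag)
        mass = monoisotopic_mass(formula)
        mzs = {
            str(z): mz_negative(mass, z)
            for z in charges
            if mass > z * PROTON_MASS
            and scan_window[0] <= mz_negative(mass, z) <= scan_window[1]
        }
        rows.append(
            {
                "parent": frag.parent_name,
                "start": frag.start,
                "end": frag.end,
                "sequence": frag.to_string(),
                "five_prime": frag.five_prime,
                "three_prime": frag.three_prime,
                "formula": formula.hill(),
                "monoisotopic_mass": mass,
                "mz_by_charge": mzs,
            }
        )
    return {
        "scan_window": list(scan_window),
        "fragments": rows,
        "matches": [
            {
                "start": m.fragment.start,
                "end": m.fragment.end,
                "charge": m.charge,
                "theoretical_mz": m.theoretical_mz,
                "observed_mz": m.observed_mz,
                "error_ppm": m.error_ppm,
            }
            for m in matches
        ],
    }
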