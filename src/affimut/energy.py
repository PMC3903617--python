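"""Nonbonded antibody-antigen interaction energy (the affinity surrogate).

The score is the sum of a Coulomb term (uniform dielectric, default 80 to
mimic water) and a 12-6 Lennard-Jones term over all cross-partner atom
pairs.  Parameters come from a bundled united-atom table: hydrogens are
omitted and their partial charges folded into the bonded heavy atoms, which
keeps the model desk-scale while preserving the charge-complementarity
signal that dominates interface energetics.

Combining rules: rmin_ij = rmin_i + rmin_j (per-atom values are rmin/2),
eps_ij = sqrt(eps_i * eps_j).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .constants import COULOMB_KCAL, DIELECTRIC_DEFAULT
from .structure import ComplexStructure

_MIN_DISTANCE = 1e-6  # Angstrom; below this a pair is a hard clash


class ClashError(ValueError):
    """Two atoms at (near-)zero separation: energies are undefined."""


class ParameterError(KeyError):
    """Missing force-field parameters for a residue or atom."""


@dataclass(frozen=True)
class EnergyBreakdown:
    """Electrostatic, van der Waals and total cross-partner energy, kcal/mol."""

    e_elec: float
    e_vdw: float

    @property
    def e_total(self) -> float:
        return self.e_elec + self.e_vdw

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.e_elec, self.e_vdw, self.e_total)


@dataclass
class EnergyModelConfig:
    """Electrostatics/LJ evaluation settings.

    ``nonbonded_cutoff`` of ``None`` means the exact full double sum
    (complexes here are small); a finite cutoff truncates with no switching
    function.
    """

    dielectric: float = DIELECTRIC_DEFAULT
    coulomb_constant: float = COULOMB_KCAL
    nonbonded_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.nonbonded_cutoff is not None and self.nonbonded_cutoff <= 0:
            raise ValueError("cutoff must be positive or None")


class ForceFieldParams:
    """Per (residue name, atom name) nonbonded parameters.

    Loaded from a whitespace-delimited text table with columns
    residue / atom / charge (e) / rmin2 (A) / eps (kcal/mol) / radius (A).
    """

    def __init__(self, table: dict[tuple[str, str], tuple[float, float, float, float]]):
        self.table = table
        self._validate()

    def _validate(self) -> None:
        sums: dict[str, float] = {}
        for (res, atom), (q, rmin2, eps, radius) in self.table.items():
            if eps < 0 or rmin2 <= 0 or radius <= 0:
                raise ValueError(f"bad LJ/radius parameters for {res}.{atom}")
            if atom != "OXT":
                sums[res] = sums.get(res, 0.0) + q
        formal = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}
        for res, total in sums.items():
            expect = formal.get(res, 0.0)
            if abs(total - expect) > 1e-3:
                raise ValueError(
                    f"residue {res} charges sum to {total:.4f}, expected {expect}")

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, atom, q, rmin2, eps, radius = line.split()
                table[(res, atom)] = (float(q), float(rmin2), float(eps), float(radius))
        return cls(table)

    @classmethod
    def default(cls) -> "ForceFieldParams":
        ref = resources.files("affimut.data") / "forcefield_united_v1.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def lookup(self, res_name: str, atom_name: str):
        return self.table.get((res_name, atom_name))


def parameterize(
    structure: ComplexStructure,
    params: ForceFieldParams | None = None,
    mode: str = "strict",
) -> list[str]:
    """Assign charge/LJ/radius to every atom in place.

    Hydrogens (absent from the united-atom table) get zero parameters and
    therefore do not contribute to the nonbonded score.  Returns the list
    of unresolved heavy-atom labels; in ``strict`` mode any unresolved atom
    raises :class:`ParameterError`, in ``permissive`` mode they are zeroed.
    """
    if params is None:
        params = ForceFieldParams.default()
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown mode {mode!r}")
    unresolved: list[str] = []
    for res in structure.residues():
        for atom in res.atoms:
            if atom.is_hydrogen:
                atom.charge = atom.lj_rmin = atom.lj_eps = 0.0
                atom.radius = 1.1
                continue
            entry = params.lookup(res.name, atom.name)
            if entry is None:
                unresolved.append(f"{res.label}:{res.name}.{atom.name}")
                atom.charge = atom.lj_rmin = atom.lj_eps = 0.0
                atom.radius = 1.7
                continue
            atom.charge, atom.lj_rmin, atom.lj_eps, atom.radius = entry
    if unresolved and mode == "strict":
        raise ParameterError(f"unparameterized atoms: {unresolved[:5]}"
                             + ("..." if len(unresolved) > 5 else ""))
    return unresolved


def _gather(structure: ComplexStructure, partner: str):
    atoms = structure.atoms(partner)
    if not atoms:
        raise ValueError(f"partner {partner} has no atoms")
    pos = np.array([a.position for a in atoms])
    q = np.array([a.charge for a in atoms])
    rmin = np.array([a.lj_rmin for a in atoms])
    eps = np.array([a.lj_eps for a in atoms])
    return atoms, pos, q, rmin, eps


def _cross_distances(structure: ComplexStructure):
    # canonical partner order (by smallest chain id) so that swapping the
    # A/B labels reproduces the sums bit-identically
    first, second = "A", "B"
    if min(structure.partner_chains("A")) > min(structure.partner_chains("B")):
        first, second = "B", "A"
    atoms_a, pa, qa, ra, ea = _gather(structure, first)
    atoms_b, pb, qb, rb, eb = _gather(structure, second)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    if d.min() < _MIN_DISTANCE:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ClashError(
            f"zero distance between {atoms_a[i].name} (A) and {atoms_b[j].name} (B)")
    return d, (qa, qb), (ra, rb), (ea, eb)


def coulomb_energy(structure: ComplexStructure,
                   config: EnergyModelConfig | None = None) -> float:
    """Cross-partner Coulomb energy, kcal/mol."""
    config = config or EnergyModelConfig()
    d, (qa, qb), _, _ = _cross_distances(structure)
    e = config.coulomb_constant * np.outer(qa, qb) / (config.dielectric * d)
    if config.nonbonded_cutoff is not None:
        e = np.where(d <= config.nonbonded_cutoff, e, 0.0)
    return float(e.sum())


def lj_energy(structure: ComplexStructure,
              config: EnergyModelConfig | None = None) -> float:
    """Cross-partner 12-6 Lennard-Jones energy, kcal/mol."""
    config = config or EnergyModelConfig()
    d, _, (ra, rb), (ea, eb) = _cross_distances(structure)
    rmin_ij = ra[:, None] + rb[None, :]
    eps_ij = np.sqrt(np.outer(ea, eb))
    with np.errstate(divide="ignore"):
        ratio6 = np.where(rmin_ij > 0, (rmin_ij / d) ** 6, 0.0)
    e = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
    if config.nonbonded_cutoff is not None:
        e = np.where(d <= config.nonbonded_cutoff, e, 0.0)
    return float(e.sum())


def interaction_energy(structure: ComplexStructure,
                       config: EnergyModelConfig | None = None) -> EnergyBreakdown:
    """Total cross-partner interaction energy breakdown.

    Intra-partner pairs never contribute; swapping the partner labels gives
    a bit-identical result because both terms are symmetric sums.
    """
    config = config or EnergyModelConfig()
    return EnergyBreakdown(
        e_elec=coulomb_energy(structure, config),
        e_vdw=lj_energy(structure, config),
    )
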