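"""Seeded synthetic-data generators.

Every pipeline stage gets a self-contained test bed with known ground
truth:

* toy two-chain complexes built from ideal alpha-helices with side chains
  from the rotamer library, with a controllable "planted" residue pair at
  the interface (stands in for an external crystal structure);
* a planted charge-complementarity benchmark with a brute-force rotamer
  enumeration oracle for the screening stage;
* temperature-series kinetics generated from chosen (dH0, dS0, dHa, dSa)
  with multiplicative lognormal noise;
* Langmuir 1:1 sensorgrams with additive Gaussian noise.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_OVER_H, R_KCAL
from .energy import ForceFieldParams, interaction_energy, parameterize
from .kinthermo import KineticRecord, Sensorgram
from .mutate import (N_CHI, MutationSpec, RotamerLibrary, build_side_chain,
                     mutate_residue, place_atom)
from .structure import (AA1_TO_3, Atom, ComplexStructure, Residue,
                        StructureError, write_pdb)

# ideal backbone internal coordinates (alpha helix)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.6, 121.7, 120.5


@dataclass
class ToyComplexSpec:
    """Two facing ideal helices with an optional planted interface pair.

    ``planted`` is (residue number on A, residue number on B, target
    CB-CB anchor distance in Angstrom between the two sites); when unset
    the chains sit at ``separation`` between helix axes.  An anchor
    distance around 9-10 A lets long charged side chains (Arg/Lys/Glu)
    reach salt-bridge range while short ones stay distant.
    """

    seq_a: str = "ASASASAS"
    seq_b: str = "ASASASAS"
    separation: float = 10.0
    planted: tuple[int, int, float] | None = None
    rotamer_policy: object = "most_probable"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        for seq in (self.seq_a, self.seq_b):
            for aa in seq:
                if aa not in AA1_TO_3:
                    raise StructureError(f"unsupported residue code {aa!r}")


def _build_helix_chain(seq: str, chain_id: str, library: RotamerLibrary,
                       policy, rng) -> list[Residue]:
    """Ideal alpha-helix backbone along ~x with template side chains."""
    residues: list[Residue] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, _B_CA_C, _A_N_CA_C, 150.0)
    for i, aa in enumerate(seq):
        name3 = AA1_TO_3[aa]
        res = Residue(name3, chain_id, i + 1)
        n_next = place_atom(n, ca, c, _B_C_N, _A_CA_C_N, _PSI)
        o = place_atom(n_next, ca, c, _B_C_O, _A_CA_C_O, 180.0)
        res.atoms = [
            Atom("N", "N", n.copy()), Atom("CA", "C", ca.copy()),
            Atom("C", "C", c.copy()), Atom("O", "O", o.copy()),
        ]
        if name3 != "GLY":
            chis = library.select(name3, policy, rng) if N_CHI[name3] else ()
            build_side_chain(res, chis, keep_cb=False)
        residues.append(res)
        ca_next = place_atom(ca, c, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = place_atom(c, n_next, ca_next, _B_CA_C, _A_N_CA_C, _PHI)
        n, ca, c = n_next, ca_next, c_next
    return residues


def _canonicalize_helix(residues: list[Residue]) -> None:
    """Rigidly move a helical chain so its axis is +x through the origin.

    The axis direction comes from cross products of successive second
    differences of the CA trace (purely radial for an ideal helix); the
    axis location from the per-residue circle centers.
    """
    ca = np.array([r.atom("CA").position for r in residues])
    if len(ca) < 5:
        return  # too short to define an axis; leave as built
    d = np.diff(ca, axis=0)
    s = d[1:] - d[:-1]
    crosses = np.cross(s[:-1], s[1:])
    u = crosses.mean(axis=0)
    u /= np.linalg.norm(u)
    if np.dot(u, d.mean(axis=0)) < 0:
        u = -u
    # rotation angle per residue from the radial second differences
    cos_t = np.clip(np.sum(s[:-1] * s[1:], axis=1)
                    / (np.linalg.norm(s[:-1], axis=1) * np.linalg.norm(s[1:], axis=1)),
                    -1.0, 1.0)
    denom = 2.0 - 2.0 * np.cos(np.arccos(cos_t).mean())
    centers = ca[1:-1] + s / denom
    p0 = centers.mean(axis=0)
    # rotate u onto ex
    ex = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ex)
    sin_a = np.linalg.norm(v)
    cos_a = float(np.dot(u, ex))
    if sin_a < 1e-12:
        rot = np.eye(3) if cos_a > 0 else np.diag([-1.0, 1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - cos_a) / sin_a ** 2)
    for res in residues:
        for a in res.atoms:
            a.position[:] = rot @ (a.position - p0)


def _anchor_coord(res: Residue) -> np.ndarray:
    name = "CB" if res.has_atom("CB") else "CA"
    return res.atom(name).position


def _rotate_x(residues: list[Residue], angle: float) -> None:
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    for res in residues:
        for a in res.atoms:
            a.position[:] = rot @ a.position


def _translate(residues: list[Residue], shift: np.ndarray) -> None:
    for res in residues:
        for a in res.atoms:
            a.position[:] = a.position + shift


def make_toy_complex(spec: ToyComplexSpec,
                     library: RotamerLibrary | None = None,
                     params: ForceFieldParams | None = None,
                     pdb_path=None) -> ComplexStructure:
    """Build a parameterized two-helix complex; optionally write a PDB.

    Chain A runs along x at z ~ 0; chain B is flipped to face it and
    shifted in +z.  With a planted pair, both chains are rotated about
    their axes so the planted side chains point at each other, and the B
    shift is tuned so their closest heavy-atom gap matches the target.
    """
    library = library or RotamerLibrary.default()
    rng = np.random.default_rng(spec.seed)
    chain_a = _build_helix_chain(spec.seq_a, "A", library, spec.rotamer_policy, rng)
    chain_b = _build_helix_chain(spec.seq_b, "B", library, spec.rotamer_policy, rng)
    _canonicalize_helix(chain_a)
    _canonicalize_helix(chain_b)

    def aim(residues, resnum, want_up: bool) -> None:
        res = next(r for r in residues if r.number == resnum)
        ca = res.atom("CA").position
        cb = res.atom("CB").position if res.has_atom("CB") else None
        if cb is None:
            return
        v = cb - ca
        angle = -math.atan2(v[1], v[2])
        if not want_up:
            angle += math.pi
        _rotate_x(residues, angle)

    if spec.planted is not None:
        pa, pb, gap = spec.planted
        aim(chain_a, pa, want_up=True)
        aim(chain_b, pb, want_up=True)
        _rotate_x(chain_b, math.pi)  # flip B to face down onto A
        res_a = next(r for r in chain_a if r.number == pa)
        res_b = next(r for r in chain_b if r.number == pb)
        # align planted sites along x/y, then tune z for the target gap
        ca_a, ca_b = res_a.atom("CA").position, res_b.atom("CA").position
        _translate(chain_b, np.array([ca_a[0] - ca_b[0], ca_a[1] - ca_b[1], 0.0]))
        _translate(chain_b, np.array([0.0, 0.0,
                                      spec.separation - res_b.atom("CA").position[2]]))

        def min_gap() -> float:
            return float(np.linalg.norm(_anchor_coord(res_a) - _anchor_coord(res_b)))

        lo, hi = -spec.separation + 1.0, 40.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            _translate(chain_b, np.array([0.0, 0.0, mid]))
            g = min_gap()
            _translate(chain_b, np.array([0.0, 0.0, -mid]))
            if g < gap:
                lo = mid
            else:
                hi = mid
        _translate(chain_b, np.array([0.0, 0.0, 0.5 * (lo + hi)]))
    else:
        _rotate_x(chain_b, math.pi)
        _translate(chain_b, np.array([0.0, 0.0, spec.separation]))

    structure = ComplexStructure({"A": chain_a, "B": chain_b}, {"A": "A", "B": "B"})
    parameterize(structure, params, mode="strict")
    if pdb_path is not None:
        write_pdb(structure, pdb_path)
    return structure


# --------------------------------------------------------------------------
# Planted charge-complementarity benchmark
# --------------------------------------------------------------------------

@dataclass
class MutationBenchmark:
    structure: ComplexStructure
    site: tuple[str, int]
    facing_residue: str
    favorable: set[str]
    unfavorable: set[str]
    oracle_delta_e: dict[str, float]
    wt_energy: float


def plant_mutation_benchmark(
    seed: int = 0,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
    gap: float = 9.5,
) -> MutationBenchmark:
    """Toy complex where the mutable site faces a glutamate on the antigen.

    The oracle delta-E for each of the 19 substitutions is computed by
    exhaustive rotamer enumeration in a static environment (no
    minimization): for each target, the best (lowest-energy) rotamer's
    interaction energy minus the wild-type complex energy.  Positively
    charged targets (Arg/Lys) are the planted favorable set, negatively
    charged ones (Asp/Glu) the unfavorable set.
    """
    library = library or RotamerLibrary.default()
    params = params or ForceFieldParams.default()
    spec = ToyComplexSpec(
        seq_a="ASASSASA", seq_b="ASAEASA",
        separation=9.0, planted=(5, 4, gap), seed=seed,
    )
    structure = make_toy_complex(spec, library=library, params=params)
    site = ("A", 5)
    wt3 = structure.get_residue(*site).name
    wt_e = interaction_energy(structure).e_total

    oracle: dict[str, float] = {}
    from .structure import STANDARD_AA3
    for target in STANDARD_AA3:
        if target == wt3 or target == "PRO":
            continue
        n_rot = len(library.rotamers.get(target, [])) or 1
        best = math.inf
        for k in range(1, n_rot + 1):
            try:
                mut = mutate_residue(
                    structure, MutationSpec("A", site[1], target, k),
                    library=library, params=params)
                e = interaction_energy(mut).e_total
            except (StructureError, ValueError):
                continue
            if math.isfinite(e):
                best = min(best, e)
        if math.isfinite(best):
            oracle[target] = best - wt_e
    return MutationBenchmark(
        structure=structure, site=site, facing_residue="GLU",
        favorable={"ARG", "LYS"}, unfavorable={"ASP", "GLU"},
        oracle_delta_e=oracle, wt_energy=wt_e,
    )


# --------------------------------------------------------------------------
# Kinetics / sensorgram simulation
# --------------------------------------------------------------------------

@dataclass
class VariantThermo:
    """Generating parameters for one variant.

    ``dh``/``ds`` are the equilibrium van't Hoff parameters (kcal/mol and
    kcal/mol/K, binding convention); ``dh_act``/``ds_act`` the Eyring
    activation parameters of association.
    """

    dh: float
    ds: float
    dh_act: float
    ds_act: float

    @classmethod
    def from_minus_t_ds(cls, dh, mtds, dh_act, mtds_act, temperature=298.15):
        return cls(dh, -mtds / temperature, dh_act, -mtds_act / temperature)


@dataclass
class KineticsSimSpec:
    variants: dict[str, VariantThermo]
    temperatures: np.ndarray = field(
        default_factory=lambda: np.linspace(283.0, 313.0, 7))
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if len(self.temperatures) < 3:
            raise ValueError("temperature grid needs >= 3 points")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")


def simulate_kinetics(spec: KineticsSimSpec) -> list[KineticRecord]:
    """Generate (variant, T, k_on, k_off) records from the thermodynamic model.

        k_on(T)  = (kB*T/h) * exp(-(dHa - T*dSa)/(R*T))
        K_D(T)   = exp((dH0 - T*dS0)/(R*T))
        k_off(T) = K_D(T) * k_on(T)

    Multiplicative lognormal noise with the given CV is applied
    independently to k_on and k_off (mean-corrected so the expectation of
    the rate is unbiased).
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2)) if spec.noise_cv > 0 else 0.0
    records: list[KineticRecord] = []
    for name, v in spec.variants.items():
        for t in spec.temperatures:
            exp_on = -(v.dh_act - t * v.ds_act) / (R_KCAL * t)
            exp_kd = (v.dh - t * v.ds) / (R_KCAL * t)
            if abs(exp_on) > 500 or abs(exp_kd) > 500:
                raise OverflowError(f"parameters overflow at T={t:.2f} K")
            k_on = KB_OVER_H * t * math.exp(exp_on)
            k_d = math.exp(exp_kd)
            k_off = k_d * k_on
            if sigma > 0:
                k_on *= math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
                k_off *= math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
            records.append(KineticRecord(name, float(t), k_on, k_off))
    return records


def simulate_sensorgram(
    k_on: float,
    k_off: float,
    r_max: float,
    concentrations,
    t_assoc: float = 300.0,
    t_diss: float = 1200.0,
    n_points: int = 200,
    noise: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Langmuir 1:1 traces (association then dissociation) + Gaussian noise.

    Association lasts ``t_assoc`` seconds (5 min default), dissociation
    ``t_diss`` (20 min default), mirroring typical SPR contact times.
    """
    if min(k_on, k_off, r_max) <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    out: list[Sensorgram] = []
    time = np.linspace(0.0, t_assoc + t_diss, n_points)
    for c in concentrations:
        if c < 0:
            raise ValueError("concentration must be >= 0")
        k_obs = k_on * c + k_off
        r_eq = r_max * c / (c + k_off / k_on) if c > 0 else 0.0
        resp = np.where(
            time <= t_assoc,
            r_eq * (1.0 - np.exp(-k_obs * time)),
            r_eq * (1.0 - math.exp(-k_obs * t_assoc))
            * np.exp(-k_off * np.maximum(time - t_assoc, 0.0)),
        )
        if noise > 0:
            resp = resp + rng.normal(0.0, noise, size=resp.shape)
        out.append(Sensorgram(float(c), time, resp, t_assoc))
    return out
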