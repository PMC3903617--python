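"""Side-chain mutagenesis, rotamer perturbation, and energy minimization.

Muteins are built with ideal internal coordinates (bundled bond lengths and
angles) and chi angles from a coarse backbone-independent rotamer library.
Backbone atoms (N, CA, C, O) and the CB anchor geometry are never moved.

Randomized model ensembles emulate side-chain microstate sampling: rotamer
prior sampling -> Gaussian chi perturbation -> cooled greedy annealing ->
Cartesian minimization of the movable side chains until the RMS energy
gradient falls below 0.01 kcal/mol/A (default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy import (ClashError, EnergyBreakdown, EnergyModelConfig,
                     ForceFieldParams, interaction_energy)
from .structure import (AA1_TO_3, BACKBONE_ATOMS, Atom, ComplexStructure,
                        Residue, StructureError)

# --------------------------------------------------------------------------
# Ideal side-chain internal coordinates.
#
# Each entry places one atom:  (name, parent, angle_ref, torsion_ref,
# bond A, angle deg, torsion spec).  The torsion is the dihedral
# (torsion_ref, angle_ref, parent, atom); specs are ("chi", k) for the k-th
# rotatable chi angle, ("off", k, delta) for a fixed offset from chi_k
# (branches), and ("abs", value) for rigid-group geometry.
# --------------------------------------------------------------------------

_CB = ("CB", "CA", "N", "C", 1.530, 110.5, ("abs", -122.5))

_PHE_RING = [
    ("CG", "CB", "CA", "N", 1.500, 113.8, ("chi", 1)),
    ("CD1", "CG", "CB", "CA", 1.390, 120.7, ("chi", 2)),
    ("CD2", "CG", "CB", "CA", 1.390, 120.7, ("off", 2, 180.0)),
    ("CE1", "CD1", "CG", "CB", 1.390, 120.0, ("abs", 180.0)),
    ("CE2", "CD2", "CG", "CB", 1.390, 120.0, ("abs", 180.0)),
    ("CZ", "CE1", "CD1", "CG", 1.390, 120.0, ("abs", 0.0)),
]

SIDECHAIN_TEMPLATES: dict[str, list] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "CB", "CA", "N", 1.417, 110.8, ("chi", 1))],
    "CYS": [_CB, ("SG", "CB", "CA", "N", 1.808, 114.4, ("chi", 1))],
    "THR": [_CB,
            ("OG1", "CB", "CA", "N", 1.433, 109.6, ("chi", 1)),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, ("off", 1, -120.0))],
    "VAL": [_CB,
            ("CG1", "CB", "CA", "N", 1.527, 110.5, ("chi", 1)),
            ("CG2", "CB", "CA", "N", 1.527, 110.5, ("off", 1, 122.0))],
    "LEU": [_CB,
            ("CG", "CB", "CA", "N", 1.530, 116.3, ("chi", 1)),
            ("CD1", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2)),
            ("CD2", "CG", "CB", "CA", 1.521, 110.7, ("off", 2, 122.0))],
    "ILE": [_CB,
            ("CG1", "CB", "CA", "N", 1.530, 110.4, ("chi", 1)),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, ("off", 1, -122.0)),
            ("CD1", "CG1", "CB", "CA", 1.513, 113.8, ("chi", 2))],
    "MET": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 114.0, ("chi", 1)),
            ("SD", "CG", "CB", "CA", 1.803, 112.7, ("chi", 2)),
            ("CE", "SD", "CG", "CB", 1.791, 100.9, ("chi", 3))],
    "PHE": [_CB] + _PHE_RING,
    "TYR": [_CB] + _PHE_RING + [
            ("OH", "CZ", "CE1", "CD1", 1.376, 119.9, ("abs", 180.0))],
    "TRP": [_CB,
            ("CG", "CB", "CA", "N", 1.500, 113.8, ("chi", 1)),
            ("CD1", "CG", "CB", "CA", 1.365, 127.0, ("chi", 2)),
            ("CD2", "CG", "CB", "CA", 1.433, 126.6, ("off", 2, 180.0)),
            ("NE1", "CD1", "CG", "CB", 1.374, 110.1, ("abs", 180.0)),
            ("CE2", "CD2", "CG", "CB", 1.409, 107.0, ("abs", 180.0)),
            ("CE3", "CD2", "CG", "CB", 1.398, 133.9, ("abs", 0.0)),
            ("CZ2", "CE2", "CD2", "CG", 1.394, 122.4, ("abs", 180.0)),
            ("CZ3", "CE3", "CD2", "CG", 1.382, 118.6, ("abs", 180.0)),
            ("CH2", "CZ2", "CE2", "CD2", 1.368, 117.5, ("abs", 0.0))],
    "ASP": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 113.0, ("chi", 1)),
            ("OD1", "CG", "CB", "CA", 1.250, 118.4, ("chi", 2)),
            ("OD2", "CG", "CB", "CA", 1.250, 118.4, ("off", 2, 180.0))],
    "ASN": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 113.0, ("chi", 1)),
            ("OD1", "CG", "CB", "CA", 1.230, 120.8, ("chi", 2)),
            ("ND2", "CG", "CB", "CA", 1.330, 116.4, ("off", 2, 180.0))],
    "GLU": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 114.0, ("chi", 1)),
            ("CD", "CG", "CB", "CA", 1.520, 114.0, ("chi", 2)),
            ("OE1", "CD", "CG", "CB", 1.250, 118.4, ("chi", 3)),
            ("OE2", "CD", "CG", "CB", 1.250, 118.4, ("off", 3, 180.0))],
    "GLN": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 114.0, ("chi", 1)),
            ("CD", "CG", "CB", "CA", 1.520, 114.0, ("chi", 2)),
            ("OE1", "CD", "CG", "CB", 1.230, 120.8, ("chi", 3)),
            ("NE2", "CD", "CG", "CB", 1.330, 116.4, ("off", 3, 180.0))],
    "HIS": [_CB,
            ("CG", "CB", "CA", "N", 1.500, 113.8, ("chi", 1)),
            ("ND1", "CG", "CB", "CA", 1.380, 122.7, ("chi", 2)),
            ("CD2", "CG", "CB", "CA", 1.360, 131.0, ("off", 2, 180.0)),
            ("CE1", "ND1", "CG", "CB", 1.320, 109.0, ("abs", 180.0)),
            ("NE2", "CD2", "CG", "CB", 1.370, 107.0, ("abs", 180.0))],
    "LYS": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 114.0, ("chi", 1)),
            ("CD", "CG", "CB", "CA", 1.520, 111.0, ("chi", 2)),
            ("CE", "CD", "CG", "CB", 1.520, 111.0, ("chi", 3)),
            ("NZ", "CE", "CD", "CG", 1.490, 111.0, ("chi", 4))],
    "ARG": [_CB,
            ("CG", "CB", "CA", "N", 1.520, 114.0, ("chi", 1)),
            ("CD", "CG", "CB", "CA", 1.520, 111.0, ("chi", 2)),
            ("NE", "CD", "CG", "CB", 1.460, 111.5, ("chi", 3)),
            ("CZ", "NE", "CD", "CG", 1.330, 124.0, ("chi", 4)),
            ("NH1", "CZ", "NE", "CD", 1.330, 120.0, ("abs", 0.0)),
            ("NH2", "CZ", "NE", "CD", 1.330, 120.0, ("abs", 180.0))],
    "PRO": [_CB,
            ("CG", "CB", "CA", "N", 1.492, 104.5, ("chi", 1)),
            ("CD", "CG", "CB", "CA", 1.503, 105.5, ("chi", 2))],
}

#: Ring-closure bonds not covered by the placement tree.
RING_CLOSURE_BONDS: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

ELEMENT_OF_ATOM = {"N": "N", "O": "O", "S": "S"}


def _n_chi(res_name: str) -> int:
    best = 0
    for entry in SIDECHAIN_TEMPLATES.get(res_name, []):
        spec = entry[6]
        if spec[0] in ("chi", "off"):
            best = max(best, spec[1])
    return best


N_CHI = {name: _n_chi(name) for name in SIDECHAIN_TEMPLATES}

#: chi-defining atom quadruples derived from the templates.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {}
for _name, _tmpl in SIDECHAIN_TEMPLATES.items():
    quads = {}
    for atom, parent, angle_ref, torsion_ref, _r, _th, spec in _tmpl:
        if spec[0] == "chi" and spec[1] not in quads:
            quads[spec[1]] = (torsion_ref, angle_ref, parent, atom)
    CHI_ATOMS[_name] = [quads[k] for k in sorted(quads)]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: position d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise StructureError("collinear reference atoms in placement")
    n = n / nn
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -math.cos(theta),
        math.sin(theta) * math.cos(tau),
        math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# --------------------------------------------------------------------------
# Rotamer library
# --------------------------------------------------------------------------

@dataclass
class RotamerLibrary:
    """Backbone-independent rotamers: per residue type, (chi tuple, prior)."""

    rotamers: dict[str, list[tuple[tuple[float, ...], float]]]

    def __post_init__(self) -> None:
        for res, entries in self.rotamers.items():
            total = sum(p for _, p in entries)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{res} rotamer priors sum to {total}, not 1")
            want = N_CHI.get(res)
            for chis, _ in entries:
                if want is not None and len(chis) != want:
                    raise ValueError(
                        f"{res} rotamer has {len(chis)} chi angles, expected {want}")

    @classmethod
    def from_file(cls, path) -> "RotamerLibrary":
        rot: dict[str, list[tuple[tuple[float, ...], float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, c1, c2, c3, c4, prob = line.split()
                chis = tuple(float(c) for c in (c1, c2, c3, c4) if c != ".")
                rot.setdefault(res, []).append((chis, float(prob)))
        return cls(rot)

    @classmethod
    def default(cls) -> "RotamerLibrary":
        ref = resources.files("affimut.data") / "rotamers_coarse_v1.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def sorted_rotamers(self, res_name: str):
        """Rotamers in descending-probability order (stable)."""
        entries = self.rotamers.get(res_name, [((), 1.0)])
        return sorted(entries, key=lambda e: -e[1])

    def select(self, res_name: str, policy, rng: np.random.Generator | None = None):
        """Pick a chi tuple: "most_probable", 1-based index int, or "sample"."""
        entries = self.sorted_rotamers(res_name)
        if policy == "most_probable":
            return entries[0][0]
        if isinstance(policy, int):
            if not 1 <= policy <= len(entries):
                raise ValueError(f"rotamer index {policy} out of range for {res_name}")
            return entries[policy - 1][0]
        if policy == "sample":
            if rng is None:
                raise ValueError("sampling policy requires an rng")
            probs = np.array([p for _, p in entries])
            k = rng.choice(len(entries), p=probs / probs.sum())
            return entries[k][0]
        raise ValueError(f"unknown rotamer policy {policy!r}")


# --------------------------------------------------------------------------
# Side-chain construction
# --------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    return ELEMENT_OF_ATOM.get(atom_name[0], "C")


def build_side_chain(residue: Residue, chis, keep_cb: bool = True) -> None:
    """(Re)build the side chain of ``residue`` in place from ideal geometry.

    Backbone atoms are untouched; an existing CB is kept as anchor when
    ``keep_cb`` and the target residue has one.  All atoms beyond the
    anchor are replaced by template-built atoms at the given chi angles.
    """
    tmpl = SIDECHAIN_TEMPLATES.get(residue.name)
    if tmpl is None:
        raise StructureError(f"no side-chain template for {residue.name}")
    chis = tuple(float(c) for c in chis)
    if len(chis) < N_CHI[residue.name]:
        raise ValueError(f"{residue.name} needs {N_CHI[residue.name]} chi angles")

    backbone = [a for a in residue.atoms if a.name in BACKBONE_ATOMS]
    have = {a.name: a for a in backbone}
    for need in ("N", "CA", "C"):
        if need not in have:
            raise StructureError(f"residue {residue.label} lacks backbone atom {need}")
    coords: dict[str, np.ndarray] = {a.name: a.position for a in backbone}
    old_cb = residue.atoms and next((a for a in residue.atoms if a.name == "CB"), None)

    new_atoms: list[Atom] = list(backbone)
    for name, parent, angle_ref, torsion_ref, bond, angle, spec in tmpl:
        if name == "CB" and keep_cb and old_cb is not None:
            coords["CB"] = old_cb.position
            new_atoms.append(old_cb)
            continue
        if spec[0] == "abs":
            tau = spec[1]
        elif spec[0] == "chi":
            tau = chis[spec[1] - 1]
        else:  # off
            tau = chis[spec[1] - 1] + spec[2]
        pos = place_atom(coords[torsion_ref], coords[angle_ref], coords[parent],
                         bond, angle, tau)
        coords[name] = pos
        new_atoms.append(Atom(name=name, element=_guess_element(name), position=pos))
    # deterministic order: backbone first (original order), then template order
    residue.atoms = new_atoms


def set_side_chain_chis(residue: Residue, chis) -> None:
    """Recompute positions of existing side-chain atoms for new chi angles.

    Atom objects are kept (positions updated in place) so array views built
    over the structure stay valid.
    """
    tmpl = SIDECHAIN_TEMPLATES.get(residue.name)
    if tmpl is None:
        raise StructureError(f"no side-chain template for {residue.name}")
    chis = tuple(float(c) for c in chis)
    coords: dict[str, np.ndarray] = {}
    for a in residue.atoms:
        coords[a.name] = a.position
    for name, parent, angle_ref, torsion_ref, bond, angle, spec in tmpl:
        if name == "CB":
            continue  # anchor
        if spec[0] == "abs":
            tau = spec[1]
        elif spec[0] == "chi":
            tau = chis[spec[1] - 1]
        else:
            tau = chis[spec[1] - 1] + spec[2]
        pos = place_atom(coords[torsion_ref], coords[angle_ref], coords[parent],
                         bond, angle, tau)
        coords[name] = pos
        residue.atom(name).position[:] = pos


def measure_chis(residue: Residue) -> list[float]:
    """Chi angles (degrees) measured from current coordinates."""
    out = []
    for quad in CHI_ATOMS.get(residue.name, []):
        pts = [residue.atom(n).position for n in quad]
        out.append(dihedral(*pts))
    return out


# --------------------------------------------------------------------------
# Mutation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """One CDR substitution: chain, author residue number, target identity."""

    chain_id: str
    number: int
    target: str  # 1- or 3-letter code
    rotamer_policy: object = "most_probable"  # or 1-based int index, or "sample"

    @property
    def target3(self) -> str:
        t = self.target.upper()
        return AA1_TO_3[t] if len(t) == 1 else t

    def mutation_id(self, wt3: str | None = None) -> str:
        from .structure import AA3_TO_1
        wt1 = AA3_TO_1.get(wt3, "X") if wt3 else "X"
        return f"{self.chain_id}-{wt1}{self.number}{AA3_TO_1.get(self.target3, 'X')}"


def mutate_residue(
    structure: ComplexStructure,
    spec: MutationSpec,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
    rng: np.random.Generator | None = None,
    allow_risky: bool = False,
) -> ComplexStructure:
    """Return a copy of the structure with one residue substituted.

    Proline targets and disulfide-bonded cysteine sites are rejected unless
    ``allow_risky`` (their geometry is not representable with a fixed
    backbone).  New atoms are parameterized with ``params``.
    """
    library = library or RotamerLibrary.default()
    target3 = spec.target3
    if target3 not in SIDECHAIN_TEMPLATES:
        raise StructureError(f"unknown target residue {spec.target}")
    if target3 == "PRO" and not allow_risky:
        raise StructureError("proline targets are rejected by default (fixed backbone)")

    out = structure.copy()
    res = out.get_residue(spec.chain_id, spec.number)
    if structure.partition.get(spec.chain_id) != "A":
        raise StructureError(f"mutation site {spec.chain_id}{spec.number} is not on partner A")
    if res.name == "CYS" and not allow_risky:
        sg = next((a for a in res.atoms if a.name == "SG"), None)
        if sg is not None:
            for other in out.residues():
                if other is res or other.name != "CYS":
                    continue
                og = next((a for a in other.atoms if a.name == "SG"), None)
                if og is not None and np.linalg.norm(og.position - sg.position) < 2.5:
                    raise StructureError(
                        f"residue {res.label} is disulfide-bonded; refusing to mutate")

    res.name = target3
    if target3 == "GLY":
        res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    else:
        chis = library.select(target3, spec.rotamer_policy, rng)
        build_side_chain(res, chis, keep_cb=True)
    from .energy import parameterize
    parameterize(out, params, mode="strict")
    return out


# --------------------------------------------------------------------------
# Minimization
# --------------------------------------------------------------------------

@dataclass
class MinimizationConfig:
    """Relaxation settings.

    ``rms_gradient_threshold`` is the convergence criterion on the RMS
    Cartesian gradient over movable atoms, kcal/mol/A.  The annealing stage
    is a cooled greedy descent in chi space before Cartesian minimization.
    """

    rms_gradient_threshold: float = 0.01
    max_steps: int = 2000
    movable_radius: float = 6.0
    #: cooled greedy chi-space descent on the mutated residue before the
    #: Cartesian minimization; 0 disables.  Off by default: it is applied
    #: only to the mutated side chain, which biases the mutant-vs-reference
    #: comparison, and the minimizer reaches the same basins without it.
    anneal_cycles: int = 0
    anneal_sigma: float = 30.0
    anneal_cooling: float = 0.8
    perturb_sigma: float = 15.0
    clash_retries: int = 3
    k_bond: float = 50.0
    k_angle13: float = 15.0
    energy_config: EnergyModelConfig = field(default_factory=EnergyModelConfig)

    def __post_init__(self) -> None:
        if self.rms_gradient_threshold <= 0:
            raise ValueError("gradient threshold must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class MinimizationTrace:
    energies: list[float]
    rms_gradient: float
    converged: bool
    n_steps: int


def _residue_bonds(res: Residue) -> list[tuple[str, str]]:
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for entry in SIDECHAIN_TEMPLATES.get(res.name, []):
        bonds.append((entry[1], entry[0]))
    bonds.extend(RING_CLOSURE_BONDS.get(res.name, []))
    present = {a.name for a in res.atoms}
    return [(a, b) for a, b in bonds if a in present and b in present]


class _System:
    """Flat-array view of a structure for fast energy/gradient evaluation."""

    def __init__(self, structure: ComplexStructure, movable_keys,
                 config: MinimizationConfig):
        self.structure = structure
        self.config = config
        atoms: list[Atom] = []
        owner: list[Residue] = []
        partner: list[str] = []
        for cid, reslist in structure.chains.items():
            lab = structure.partition[cid]
            for res in reslist:
                for a in res.atoms:
                    atoms.append(a)
                    owner.append(res)
                    partner.append(lab)
        self.atoms = atoms
        self.owner = owner
        self.pos = np.array([a.position for a in atoms])
        self.q = np.array([a.charge for a in atoms])
        self.rmin = np.array([a.lj_rmin for a in atoms])
        self.eps = np.array([a.lj_eps for a in atoms])
        self.partner = np.array([0 if p == "A" else 1 for p in partner])

        keyset = set()
        for key in movable_keys:
            keyset.add(tuple(key))
        movable = np.zeros(len(atoms), dtype=bool)
        for i, (a, res) in enumerate(zip(atoms, owner)):
            if (res.chain_id, res.number) in keyset and a.name not in BACKBONE_ATOMS:
                movable[i] = True
            if (res.chain_id, res.number, a.name) in keyset:
                movable[i] = True
        if not movable.any():
            raise ValueError("movable selection is empty")
        self.movable = movable
        self.mov_idx = np.nonzero(movable)[0]

        n = len(atoms)
        cross = self.partner[:, None] != self.partner[None, :]
        iu = np.triu_indices(n, k=1)
        mask = cross[iu]
        ii, jj = iu[0][mask], iu[1][mask]
        active = movable[ii] | movable[jj]
        self.cross_ii, self.cross_jj = ii[active], jj[active]
        self.static_ii, self.static_jj = ii[~active], jj[~active]

        # intra-partner nonbonded among movable atoms of *different* residues
        same = ~cross[iu]
        ii2, jj2 = iu[0][same], iu[1][same]
        both_mov = movable[ii2] & movable[jj2]
        diff_res = np.array([owner[a] is not owner[b]
                             for a, b in zip(ii2[both_mov], jj2[both_mov])], dtype=bool) \
            if both_mov.any() else np.array([], dtype=bool)
        self.intra_ii = ii2[both_mov][diff_res]
        self.intra_jj = jj2[both_mov][diff_res]

        # harmonic restraints: bonds and 1-3 pairs touching a movable atom,
        # with targets taken from the current (ideal, template-built) geometry
        index_of = {}
        for i, (a, res) in enumerate(zip(atoms, owner)):
            index_of[(id(res), a.name)] = i
        r_ii, r_jj, r_k = [], [], []
        seen_res = set()
        for i in self.mov_idx:
            res = owner[i]
            if id(res) in seen_res:
                continue
            seen_res.add(id(res))
            bonds = _residue_bonds(res)
            adj: dict[str, set[str]] = {}
            for a, b in bonds:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            pairs = set((min(a, b), max(a, b)) for a, b in bonds)
            for center, nbrs in adj.items():
                nl = sorted(nbrs)
                for x in range(len(nl)):
                    for y in range(x + 1, len(nl)):
                        pairs.add((min(nl[x], nl[y]), max(nl[x], nl[y])))
            strong = set((min(a, b), max(a, b)) for a, b in bonds)
            for a, b in sorted(pairs):
                ia = index_of.get((id(res), a))
                ib = index_of.get((id(res), b))
                if ia is None or ib is None:
                    continue
                if not (movable[ia] or movable[ib]):
                    continue
                r_ii.append(ia)
                r_jj.append(ib)
                r_k.append(config.k_bond if (a, b) in strong else config.k_angle13)
        self.res_ii = np.array(r_ii, dtype=int)
        self.res_jj = np.array(r_jj, dtype=int)
        self.res_k = np.array(r_k, dtype=float)
        d0 = np.linalg.norm(self.pos[self.res_ii] - self.pos[self.res_jj], axis=1) \
            if len(self.res_ii) else np.array([])
        self.res_r0 = d0

        self._e_static = self._pair_energy(self.static_ii, self.static_jj)[0] \
            if len(self.static_ii) else 0.0

        # precomputed per-pair constants for the active (cross + intra) set
        cfg = config.energy_config
        self.act_ii = np.concatenate([self.cross_ii, self.intra_ii]).astype(int)
        self.act_jj = np.concatenate([self.cross_jj, self.intra_jj]).astype(int)
        self._qqk = (cfg.coulomb_constant / cfg.dielectric
                     * self.q[self.act_ii] * self.q[self.act_jj])
        self._rmin2_sq = (self.rmin[self.act_ii] + self.rmin[self.act_jj]) ** 2
        self._epsij = np.sqrt(self.eps[self.act_ii] * self.eps[self.act_jj])
        self._cut2 = (cfg.nonbonded_cutoff ** 2
                      if cfg.nonbonded_cutoff is not None else None)

    def refresh_positions(self) -> None:
        self.pos = np.array([a.position for a in self.atoms])

    def _pair_energy(self, ii, jj, grad: bool = False):
        cfg = self.config.energy_config
        dvec = self.pos[ii] - self.pos[jj]
        d = np.linalg.norm(dvec, axis=1)
        if len(d) and d.min() < 1e-6:
            raise ClashError("zero interatomic distance during minimization")
        e_c = cfg.coulomb_constant * self.q[ii] * self.q[jj] / (cfg.dielectric * d)
        rmin_ij = self.rmin[ii] + self.rmin[jj]
        eps_ij = np.sqrt(self.eps[ii] * self.eps[jj])
        with np.errstate(divide="ignore"):
            ratio6 = np.where(rmin_ij > 0, (rmin_ij / d) ** 6, 0.0)
        e_lj = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
        if cfg.nonbonded_cutoff is not None:
            inside = d <= cfg.nonbonded_cutoff
            e_c = np.where(inside, e_c, 0.0)
            e_lj = np.where(inside, e_lj, 0.0)
        e = float(e_c.sum() + e_lj.sum())
        if not grad:
            return e, None
        de_c = -e_c / d
        de_lj = eps_ij * 12.0 / d * (ratio6 - ratio6 ** 2)
        if cfg.nonbonded_cutoff is not None:
            de_lj = np.where(d <= cfg.nonbonded_cutoff, de_lj, 0.0)
            de_c = np.where(d <= cfg.nonbonded_cutoff, de_c, 0.0)
        dd = ((de_c + de_lj) / d)[:, None] * dvec
        n = len(self.pos)
        g = np.empty_like(self.pos)
        for k in range(3):
            g[:, k] = (np.bincount(ii, weights=dd[:, k], minlength=n)
                       - np.bincount(jj, weights=dd[:, k], minlength=n))
        return e, g

    def _restraint_energy(self, grad: bool = False):
        if not len(self.res_ii):
            return 0.0, (np.zeros_like(self.pos) if grad else None)
        dvec = self.pos[self.res_ii] - self.pos[self.res_jj]
        d = np.linalg.norm(dvec, axis=1)
        diff = d - self.res_r0
        e = float(np.sum(self.res_k * diff ** 2))
        if not grad:
            return e, None
        dd = (2.0 * self.res_k * diff / np.maximum(d, 1e-12))[:, None] * dvec
        n = len(self.pos)
        g = np.empty_like(self.pos)
        for k in range(3):
            g[:, k] = (np.bincount(self.res_ii, weights=dd[:, k], minlength=n)
                       - np.bincount(self.res_jj, weights=dd[:, k], minlength=n))
        return e, g

    def objective(self, x: np.ndarray | None = None, grad: bool = False):
        if x is not None:
            self.pos[self.mov_idx] = x.reshape(-1, 3)
        ii, jj = self.act_ii, self.act_jj
        dvec = self.pos[ii] - self.pos[jj]
        d2 = np.einsum("ij,ij->i", dvec, dvec)
        if len(d2) and d2.min() < 1e-12:
            raise ClashError("zero interatomic distance during minimization")
        inv_d2 = 1.0 / d2
        e_c = self._qqk * np.sqrt(inv_d2)
        r6 = (self._rmin2_sq * inv_d2) ** 3
        e_lj = self._epsij * (r6 * r6 - 2.0 * r6)
        if self._cut2 is not None:
            inside = d2 <= self._cut2
            e_c = np.where(inside, e_c, 0.0)
            e_lj = np.where(inside, e_lj, 0.0)
        e3, g3 = self._restraint_energy(grad)
        e = float(e_c.sum() + e_lj.sum()) + e3 + self._e_static
        if not grad:
            return e
        coef = -e_c * inv_d2 + 12.0 * self._epsij * (r6 - r6 * r6) * inv_d2
        if self._cut2 is not None:
            coef = np.where(d2 <= self._cut2, coef, 0.0)
        dd = coef[:, None] * dvec
        n = len(self.pos)
        g = g3
        for k in range(3):
            g[:, k] += (np.bincount(ii, weights=dd[:, k], minlength=n)
                        - np.bincount(jj, weights=dd[:, k], minlength=n))
        return e, g[self.mov_idx].ravel()

    def write_back(self) -> None:
        for i, a in enumerate(self.atoms):
            a.position[:] = self.pos[i]

    def rms_gradient(self) -> float:
        _, g = self.objective(grad=True)
        return float(np.sqrt(np.mean(g ** 2)))

    def cross_breakdown(self):
        """(e_elec, e_vdw, min distance) over every cross-partner pair."""
        cfg = self.config.energy_config
        ii = np.concatenate([self.cross_ii, self.static_ii])
        jj = np.concatenate([self.cross_jj, self.static_jj])
        dvec = self.pos[ii] - self.pos[jj]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        e_c = cfg.coulomb_constant * self.q[ii] * self.q[jj] / (cfg.dielectric * d)
        rmin_ij = self.rmin[ii] + self.rmin[jj]
        eps_ij = np.sqrt(self.eps[ii] * self.eps[jj])
        r6 = np.where(rmin_ij > 0, (rmin_ij / d) ** 6, 0.0)
        e_lj = eps_ij * (r6 * r6 - 2.0 * r6)
        if cfg.nonbonded_cutoff is not None:
            inside = d <= cfg.nonbonded_cutoff
            e_c = np.where(inside, e_c, 0.0)
            e_lj = np.where(inside, e_lj, 0.0)
        heavy = (self.rmin[ii] > 0) & (self.rmin[jj] > 0)
        dmin = float(d[heavy].min()) if heavy.any() else float(d.min())
        return float(e_c.sum()), float(e_lj.sum()), dmin


def movable_selection_around(
    structure: ComplexStructure,
    site: tuple[str, int],
    radius: float = 6.0,
) -> list[tuple[str, int]]:
    """Residues (either partner) with a heavy atom within ``radius`` of the
    site's side chain, the site itself included; side chains only move."""
    res0 = structure.get_residue(*site)
    ref = np.array([a.position for a in res0.heavy_atoms()
                    if a.name not in ("N", "C", "O")])
    if len(ref) == 0:
        ref = np.array([a.position for a in res0.heavy_atoms()])
    keys = [site]
    for res in structure.residues():
        if res is res0:
            continue
        pts = np.array([a.position for a in res.heavy_atoms()])
        if len(pts) == 0:
            continue
        dmin = np.min(np.linalg.norm(pts[:, None, :] - ref[None, :, :], axis=-1))
        if dmin <= radius:
            keys.append((res.chain_id, res.number))
    return keys


def minimize(
    structure: ComplexStructure,
    movable_selection,
    config: MinimizationConfig | None = None,
    system: "_System | None" = None,
) -> tuple[ComplexStructure, MinimizationTrace]:
    """Relax movable side-chain atoms by quasi-Newton descent.

    Objective: cross-partner nonbonded energy + nonbonded energy among
    movable atoms of different residues + harmonic restraints keeping
    bond lengths and 1-3 distances at their ideal values.  Backbones never
    move.  Stops when the RMS Cartesian gradient over movable atoms falls
    below the configured threshold (energy trace is non-increasing).
    The structure is modified in place and also returned.
    """
    config = config or MinimizationConfig()
    sys_ = system if system is not None else _System(structure, movable_selection, config)

    e0 = sys_.objective()
    if not np.isfinite(e0):
        raise ClashError("non-finite energy at minimization start")

    if sys_.rms_gradient() < config.rms_gradient_threshold:
        trace = MinimizationTrace([e0], sys_.rms_gradient(), True, 0)
        return structure, trace

    # diagonal preconditioning: stiff harmonic restraints vs soft nonbonded
    # modes make the plain problem ill-conditioned
    n_mov = len(sys_.mov_idx)
    h_diag = np.full(n_mov, 10.0)
    if len(sys_.res_ii):
        pos_in_mov = {int(g): k for k, g in enumerate(sys_.mov_idx)}
        for ia, ib, kk in zip(sys_.res_ii, sys_.res_jj, sys_.res_k):
            for idx in (int(ia), int(ib)):
                if idx in pos_in_mov:
                    h_diag[pos_in_mov[idx]] += 2.0 * kk
    scale = np.sqrt(np.repeat(h_diag, 3))

    energies = [e0]
    last = {"g": None, "x": None, "e": e0}

    def fun(y):
        x = y / scale
        e, g = sys_.objective(x, grad=True)
        if e <= last["e"]:
            last.update(g=g, x=x.copy(), e=e)
        return e, g / scale

    def callback(yk):
        energies.append(min(last["e"], energies[-1]))
        # the optimizer's own test is on max|g|; stop at the RMS criterion
        # evaluated on the unscaled Cartesian gradient
        if last["g"] is not None and \
                float(np.sqrt(np.mean(last["g"] ** 2))) < config.rms_gradient_threshold:
            raise StopIteration

    x0 = sys_.pos[sys_.mov_idx].ravel().copy()
    res = _scipy_minimize(
        fun, x0 * scale, jac=True, method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_steps,
            "gtol": 0.0,
            "ftol": 1e-14,
        },
    )
    x_best = res.x / scale if res.fun <= last["e"] or last["x"] is None else last["x"]
    sys_.objective(x_best)
    sys_.write_back()
    rms = sys_.rms_gradient()
    converged = rms < config.rms_gradient_threshold
    trace = MinimizationTrace(energies, rms, converged, int(res.nit))
    return structure, trace


def perturb_sidechain(
    structure: ComplexStructure,
    site: tuple[str, int],
    sigma_degrees: float,
    rng: np.random.Generator,
) -> ComplexStructure:
    """Gaussian chi-angle perturbation of one residue, in place.

    Deterministic under a fixed rng state; sigma of 0 leaves coordinates
    unchanged.  Residues without chi angles are left untouched.
    """
    res = structure.get_residue(*site)
    nchi = N_CHI.get(res.name, 0)
    if nchi == 0:
        return structure
    chis = np.array(measure_chis(res))
    if sigma_degrees > 0:
        chis = chis + rng.normal(0.0, sigma_degrees, size=len(chis))
    set_side_chain_chis(res, chis)
    return structure


# --------------------------------------------------------------------------
# Ensembles
# --------------------------------------------------------------------------

@dataclass
class ModelRecord:
    structure: ComplexStructure | None
    energy: EnergyBreakdown | None
    converged: bool
    n_steps: int
    reason: str = ""
    #: smallest cross-partner heavy-atom distance in the relaxed model, A
    min_cross_distance: float = math.inf


@dataclass
class ModelEnsemble:
    """Randomized relaxed models of one mutation (or of the wild type)."""

    mutation_id: str
    models: list[ModelRecord]
    seed: int

    def energies(self) -> list[float]:
        return [m.energy.e_total for m in self.models if m.energy is not None]

    def n_converged(self) -> int:
        return sum(1 for m in self.models if m.converged)


def _anneal_chis(structure, sys_: _System, res: Residue, config, rng) -> None:
    """Cooled greedy descent over the mutated residue's chi angles."""
    nchi = N_CHI.get(res.name, 0)
    if nchi == 0:
        return
    sigma = config.anneal_sigma
    sys_.refresh_positions()
    best = sys_.objective()
    chis = np.array(measure_chis(res))
    for _ in range(config.anneal_cycles):
        prop = chis + rng.normal(0.0, sigma, size=nchi)
        set_side_chain_chis(res, prop)
        sys_.refresh_positions()
        try:
            e = sys_.objective()
        except ClashError:
            e = np.inf
        if np.isfinite(e) and e < best:
            best, chis = e, prop
        else:
            set_side_chain_chis(res, chis)
            sys_.refresh_positions()
        sigma *= config.anneal_cooling


def build_ensemble(
    structure: ComplexStructure,
    spec: MutationSpec | None,
    n_models: int,
    config: MinimizationConfig | None = None,
    seed: int = 0,
    library: RotamerLibrary | None = None,
    params: ForceFieldParams | None = None,
    movable_keys=None,
    keep_structures: bool = False,
) -> ModelEnsemble:
    """Generate ``n_models`` randomized relaxed models and score them.

    With a :class:`MutationSpec` the residue is substituted first (rotamer
    sampled from the library prior unless the spec pins a policy); with
    ``spec=None`` the wild-type structure is perturbed/relaxed as-is (the
    reference ensemble).  Per-model randomness derives from ``seed``;
    results are bit-reproducible.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    config = config or MinimizationConfig()
    library = library or RotamerLibrary.default()
    records: list[ModelRecord] = []
    children = np.random.SeedSequence(seed).spawn(n_models)

    # the mutant (or wild-type) template is built once; models differ only
    # in side-chain conformations, so one numeric system serves them all
    site = res = None
    if spec is not None:
        wt3 = structure.get_residue(spec.chain_id, spec.number).name
        mutation_id = spec.mutation_id(wt3)
        policy = spec.rotamer_policy
        base_policy = "most_probable" if policy in ("sample", None) else policy
        template = mutate_residue(structure, MutationSpec(
            spec.chain_id, spec.number, spec.target, base_policy),
            library=library, params=params)
        site = (spec.chain_id, spec.number)
        keys = movable_keys or movable_selection_around(
            template, site, config.movable_radius)
        res = template.get_residue(*site)
        sample_rotamer = policy in ("sample", None)
    else:
        mutation_id = "WT"
        if movable_keys is None:
            raise ValueError("wild-type ensembles need explicit movable_keys")
        template = structure.copy()
        keys = movable_keys
        sample_rotamer = False

    sys_ = _System(template, keys, config)
    pos0 = sys_.pos.copy()
    movable_res = sorted({(sys_.owner[i].chain_id, sys_.owner[i].number)
                          for i in sys_.mov_idx})

    for child in children:
        rng = np.random.default_rng(child)
        try:
            for i, a in enumerate(sys_.atoms):  # reset to template coords
                a.position[:] = pos0[i]
            # symmetric randomization: every movable side chain is resampled
            # from the rotamer prior and jittered, wild-type and mutant alike
            # (a pinned rotamer policy on the mutated site is honored)
            for key in movable_res:
                r_ = template.get_residue(*key)
                if N_CHI.get(r_.name, 0) == 0:
                    continue
                if key == site and not sample_rotamer:
                    pass  # keep the pinned rotamer; jitter only
                else:
                    set_side_chain_chis(r_, library.select(r_.name, "sample", rng))
                perturb_sidechain(template, key, config.perturb_sigma, rng)
            sys_.refresh_positions()

            ok = False
            for _ in range(config.clash_retries + 1):
                try:
                    if np.isfinite(sys_.objective()):
                        ok = True
                        break
                except ClashError:
                    pass
                retry_key = site if site is not None else movable_res[0]
                perturb_sidechain(template, retry_key, config.anneal_sigma, rng)
                sys_.refresh_positions()
            if not ok:
                records.append(ModelRecord(None, None, False, 0, "unresolvable clash"))
                continue

            if res is not None:
                _anneal_chis(template, sys_, res, config, rng)
            _, trace = minimize(template, keys, config, system=sys_)
            e_elec, e_vdw, dmin = sys_.cross_breakdown()
            records.append(ModelRecord(
                template.copy() if keep_structures else None,
                EnergyBreakdown(e_elec, e_vdw), trace.converged, trace.n_steps,
                min_cross_distance=dmin))
        except ClashError as exc:
            records.append(ModelRecord(None, None, False, 0, f"clash: {exc}"))

    if not any(m.energy is not None for m in records):
        raise RuntimeError(
            f"all {n_models} models failed for {mutation_id}: "
            + "; ".join(sorted({m.reason for m in records})))
    return ModelEnsemble(mutation_id, records, seed)
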