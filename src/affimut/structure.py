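"""Protein complex structures with a declared antibody/antigen partition.

Coordinates use author (PDB) residue numbering, 1-based, inclusive ranges;
no silent renumbering is ever performed.  Atoms additionally carry nonbonded
force-field parameters (assigned by :mod:`affimut.energy`) and a van der
Waals radius used for surface-area calculations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


class StructureError(ValueError):
    """Malformed structure or violated structural precondition."""


@dataclass
class Atom:
    """A single atom with coordinates and nonbonded parameters.

    ``charge`` is in elementary-charge units; ``lj_rmin`` is the per-atom
    rmin/2 Lennard-Jones parameter in Angstrom; ``lj_eps`` the well depth in
    kcal/mol; ``radius`` the van der Waals radius used for SASA.
    Parameters default to zero until :func:`affimut.energy.parameterize`
    assigns them.
    """

    name: str
    element: str
    position: np.ndarray
    charge: float = 0.0
    lj_rmin: float = 0.0
    lj_eps: float = 0.0
    radius: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: bad position {self.position}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    """One residue: 3-letter name, chain id, author number + insertion code."""

    name: str
    chain_id: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.number}{self.icode}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.label} ({self.name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(self.name, self.chain_id, self.number, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class ComplexStructure:
    """A two-partner complex: chains plus a chain->partner-label partition.

    ``partition`` maps each chain id to ``"A"`` (antibody) or ``"B"``
    (antigen).  Both partner labels must be populated for interface and
    energy operations.
    """

    chains: dict[str, list[Residue]]
    partition: dict[str, str]

    def __post_init__(self) -> None:
        for cid, label in self.partition.items():
            if label not in ("A", "B"):
                raise StructureError(f"partition label for chain {cid} must be 'A' or 'B'")

    def residues(self, partner: str | None = None) -> list[Residue]:
        out: list[Residue] = []
        for cid, reslist in self.chains.items():
            if partner is None or self.partition.get(cid) == partner:
                out.extend(reslist)
        return out

    def atoms(self, partner: str | None = None) -> list[Atom]:
        return [a for r in self.residues(partner) for a in r.atoms]

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.chains.get(chain_id, []):
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}{number}{icode} in structure")

    def partner_chains(self, label: str) -> list[str]:
        return [c for c, lab in self.partition.items() if lab == label]

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            {cid: [r.copy() for r in rl] for cid, rl in self.chains.items()},
            dict(self.partition),
        )

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


@dataclass
class CdrSelection:
    """Mutable (CDR) residues: (chain_id, residue number) pairs + provenance."""

    residues: list[tuple[str, int]]
    scheme: str = "user list"


def read_pdb(
    path,
    partition_spec: dict[str, str],
    *,
    keep_het: bool = False,
    altloc_policy: str = "first",
) -> ComplexStructure:
    """Read a PDB (or mmCIF) file into a :class:`ComplexStructure`.

    Every polymer chain present in the file must be assigned to partner
    ``"A"`` or ``"B"`` by ``partition_spec``.  Waters and HETATM residues
    are skipped unless ``keep_het``.  Alternate locations: keep blank or
    'A', drop the rest (logged).  Duplicate atom names within a residue:
    warn and keep the first.
    """
    if altloc_policy != "first":
        raise ValueError(f"unsupported altloc policy {altloc_policy!r}; "
                         "only 'first' (keep blank or 'A') is implemented")
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    n_altloc_dropped = 0
    for chain in model:
        cid = chain.name
        reslist: list[Residue] = []
        for res in chain:
            is_standard = res.name in STANDARD_AA3
            if not is_standard and not keep_het:
                continue
            if res.name == "HOH" and not keep_het:
                continue
            atoms: list[Atom] = []
            seen: set[str] = set()
            for at in res:
                if at.altloc not in ("", "\x00", "A"):
                    n_altloc_dropped += 1
                    continue
                if at.name in seen:
                    warnings.warn(
                        f"duplicate atom {at.name} in {cid}{res.seqid.num}; keeping first"
                    )
                    continue
                seen.add(at.name)
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    altloc="" if at.altloc in ("", "\x00") else at.altloc,
                ))
            if atoms:
                icode = res.seqid.icode.strip()
                reslist.append(Residue(res.name, cid, res.seqid.num, icode, atoms))
        if reslist:
            chains[cid] = reslist

    if n_altloc_dropped:
        logger.info("dropped %d alternate-location atoms", n_altloc_dropped)

    missing = [c for c in partition_spec if c not in chains]
    if missing:
        raise StructureError(f"partition chains absent from file: {missing}")
    unassigned = [c for c in chains if c not in partition_spec]
    if unassigned:
        raise StructureError(f"chains not assigned to a partner: {unassigned}")
    return ComplexStructure(chains, dict(partition_spec))


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write standard fixed-column PDB ATOM records (author numbering kept)."""
    if structure.n_residues() == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "affimut"
    model = gemmi.Model("1")
    for cid, reslist in structure.chains.items():
        chain = gemmi.Chain(cid)
        for res in reslist:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode if res.icode else " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                ga.b_iso = 0.0
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)


def select_cdr(
    structure: ComplexStructure,
    ranges_or_list,
    scheme: str = "user list",
) -> CdrSelection:
    """Select mutable residues on partner A.

    ``ranges_or_list`` is either a list of ``(chain_id, start, end)`` range
    triples (author numbering, inclusive on both ends) or an explicit list
    of ``(chain_id, number)`` pairs, which is passed through after an
    existence check.
    """
    if not ranges_or_list:
        raise StructureError("empty CDR specification")
    first = ranges_or_list[0]
    selected: list[tuple[str, int]] = []
    if len(first) == 3:
        for cid, start, end in ranges_or_list:
            if structure.partition.get(cid) != "A":
                raise StructureError(f"CDR range on chain {cid}, which is not partner A")
            for res in structure.chains.get(cid, []):
                if start <= res.number <= end:
                    selected.append((cid, res.number))
    else:
        seen: set[tuple[str, int]] = set()
        for cid, num in ranges_or_list:
            if (cid, num) in seen:
                raise StructureError(f"duplicate CDR residue {cid}{num}")
            seen.add((cid, num))
            if structure.partition.get(cid) != "A":
                raise StructureError(f"CDR residue {cid}{num} is not on partner A")
            structure.get_residue(cid, num)  # existence check
            selected.append((cid, num))
    return CdrSelection(selected, scheme)


def load_cdr_ranges(scheme: str = "kabat"):
    """Bundled literature CDR ranges, ``scheme`` in {"kabat", "chothia"}.

    Returns {(domain, cdr_index): (start, end)} in Kabat numbering.  Only
    meaningful when the caller asserts the structure uses that numbering;
    the default workflow is an explicit residue list.
    """
    from importlib import resources
    ref = resources.files("affimut.data") / "cdr_ranges_kabat_chothia.tsv"
    out: dict[tuple[str, int], tuple[int, int]] = {}
    with resources.as_file(ref) as path, open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sch, domain, cdr, start, end = line.split()
            if sch == scheme:
                out[(domain, int(cdr))] = (int(start), int(end))
    if not out:
        raise ValueError(f"unknown CDR scheme {scheme!r}")
    return out


def select_cdr_by_scheme(
    structure: ComplexStructure,
    chain_domains: dict[str, str],
    scheme: str = "kabat",
) -> CdrSelection:
    """CDR selection from the bundled range table.

    ``chain_domains`` maps partner-A chain ids to "H" or "L".  The caller
    asserts the structure's author numbering follows the scheme; no
    renumbering is performed.
    """
    ranges = load_cdr_ranges(scheme)
    triples = []
    for cid, domain in chain_domains.items():
        for (dom, _cdr), (start, end) in sorted(ranges.items()):
            if dom == domain:
                triples.append((cid, start, end))
    sel = select_cdr(structure, triples)
    sel.scheme = f"{scheme} ranges, user-asserted numbering"
    return sel


def _heavy_coords_by_residue(structure: ComplexStructure, partner: str):
    residues = structure.residues(partner)
    coords, index = [], []
    for i, res in enumerate(residues):
        for atom in res.heavy_atoms():
            coords.append(atom.position)
            index.append(i)
    if not coords:
        return residues, np.empty((0, 3)), np.empty(0, dtype=int)
    return residues, np.asarray(coords), np.asarray(index, dtype=int)


def interface_residues(
    structure: ComplexStructure, cutoff: float = 4.5
) -> list[tuple[Residue, Residue]]:
    """Cross-partner residue contact pairs.

    A pair is included iff any heavy-atom cross-partner distance is within
    ``cutoff`` (Angstrom).  Ordering is deterministic: sorted by
    (chainA, numberA, chainB, numberB).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_a, xyz_a, idx_a = _heavy_coords_by_residue(structure, "A")
    res_b, xyz_b, idx_b = _heavy_coords_by_residue(structure, "B")
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        raise StructureError("both partners must contain heavy atoms")
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    hit = d <= cutoff
    pairs = set()
    ii, jj = np.nonzero(hit)
    for i, j in zip(ii, jj):
        pairs.add((idx_a[i], idx_b[j]))
    out = [(res_a[i], res_b[j]) for i, j in pairs]
    out.sort(key=lambda p: (p[0].chain_id, p[0].number, p[0].icode,
                            p[1].chain_id, p[1].number, p[1].icode))
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sasa(coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int,
          per_atom: bool = False):
    """Shrake-Rupley solvent-accessible surface area, Angstrom^2."""
    sphere = _fibonacci_sphere(n_points)
    n = len(coords)
    areas = np.zeros(n)
    rr = radii + probe
    for i in range(n):
        pts = coords[i] + rr[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        d0 = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.nonzero((d0 < rr + rr[i]) & (np.arange(n) != i))[0]
        for j in neighbors:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= dj >= rr[j]
        areas[i] = 4.0 * np.pi * rr[i] ** 2 * accessible.sum() / n_points
    return areas if per_atom else areas.sum()


def buried_surface_area(
    structure: ComplexStructure,
    *,
    probe_radius: float = 1.4,
    n_points: int = 960,
    per_residue: bool = False,
):
    """Buried surface area SASA(A) + SASA(B) - SASA(AB), Angstrom^2.

    Uses Shrake-Rupley sampling on heavy atoms; atoms must carry radii
    (assigned by parameterize).  With ``per_residue`` also returns the
    per-residue buried area attribution.
    """
    def gather(partner):
        residues = structure.residues(partner)
        coords, radii, res_idx = [], [], []
        for k, res in enumerate(residues):
            for a in res.heavy_atoms():
                if a.radius <= 0:
                    raise StructureError(
                        f"atom {a.name} in {res.label} has no radius; parameterize first")
                coords.append(a.position)
                radii.append(a.radius)
                res_idx.append((partner, res.label))
        return np.asarray(coords), np.asarray(radii), res_idx

    ca, ra, ia = gather("A")
    cb, rb, ib = gather("B")
    sasa_a = _sasa(ca, ra, probe_radius, n_points, per_atom=True)
    sasa_b = _sasa(cb, rb, probe_radius, n_points, per_atom=True)
    sasa_ab = _sasa(np.vstack([ca, cb]), np.concatenate([ra, rb]),
                    probe_radius, n_points, per_atom=True)
    buried_atoms = np.concatenate([sasa_a, sasa_b]) - sasa_ab
    bsa = float(buried_atoms.sum())
    if not per_residue:
        return bsa
    attribution: dict[tuple[str, str], float] = {}
    for val, key in zip(buried_atoms, ia + ib):
        attribution[key] = attribution.get(key, 0.0) + float(val)
    return bsa, attribution
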