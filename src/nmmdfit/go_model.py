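"""Cα structure-based (Gō) force field: topology construction and energetics.

The potential is the standard coarse-grained structure-based model whose
global minimum is the native structure used to build the topology:

    E = Σ_bonds     k_b (r − r0)²
      + Σ_angles    k_a (θ − θ0)²
      + Σ_dihedrals k_d1 [1 − cos(φ − φ0)] + k_d3 [1 − cos 3(φ − φ0)]
      + Σ_contacts  ε [5 (σij/r)¹² − 6 (σij/r)¹⁰]
      + Σ_noncontact ε_x [(r_x/r)⁶ − 1]²  for r < r_x, else 0

in reduced units (length Å, energy ε ≡ 1 kcal/mol for the temperature
mapping, mass 1 per bead).  Native contacts are pairs within a distance
cutoff and at least ``min_seq_sep`` residues apart in sequence; their
12-10 well has its minimum (−ε per contact) exactly at the native
separation σij.  All remaining pairs with sequence separation ≥ 3 repel
through a purely repulsive excluded-volume term that is truncated and
shifted to vanish smoothly at r_x, so that the native structure is an
exact stationary point of the full potential (non-contact pairs sit
beyond r_x in any reasonable native geometry).

Forces returned by :func:`go_energy_forces` are the exact analytic
negative gradient of this energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import AtomicModel

logger = logging.getLogger(__name__)

__all__ = ["GoParams", "GoTopology", "EnergyReport", "build_ca_go",
           "go_energy_forces", "write_topology", "read_topology"]

#: bond length above which consecutive residues are treated as a chain break, Å
CHAIN_BREAK_DISTANCE = 4.5


@dataclass
class GoParams:
    """Force constants of the Cα Gō model (reduced units)."""

    k_bond: float = 100.0      # ε/Å²
    k_angle: float = 20.0      # ε/rad²
    k_dihedral1: float = 1.0   # ε
    k_dihedral3: float = 0.5   # ε
    eps_contact: float = 1.0   # ε
    eps_excl: float = 1.0      # ε
    r_excl: float = 4.0        # Å
    cutoff: float = 8.0        # Å, native-contact cutoff
    min_seq_sep: int = 4


@dataclass
class EnergyReport:
    """Per-term energy breakdown; ``total`` is the sum of the terms."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    contact: float = 0.0
    excluded: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.contact + self.excluded


@dataclass
class GoTopology:
    """Bonded terms, native contacts and excluded-volume pair list."""

    bonds: np.ndarray        # (nb, 2) int indices
    bond_r0: np.ndarray      # (nb,) Å
    angles: np.ndarray       # (na, 3) int
    angle_theta0: np.ndarray  # (na,) rad
    dihedrals: np.ndarray    # (nd, 4) int
    dihedral_phi0: np.ndarray  # (nd,) rad
    contacts: np.ndarray     # (nc, 2) int
    contact_sigma: np.ndarray  # (nc,) Å
    excluded: np.ndarray     # (nx, 2) int, non-contact pairs |i−j| ≥ 3
    params: GoParams = field(default_factory=GoParams)
    n_atoms: int = 0

    def __post_init__(self) -> None:
        for name in ("bonds", "angles", "dihedrals", "contacts", "excluded"):
            arr = np.asarray(getattr(self, name), dtype=int)
            width = {"bonds": 2, "angles": 3, "dihedrals": 4,
                     "contacts": 2, "excluded": 2}[name]
            setattr(self, name, arr.reshape(-1, width))
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float).ravel()
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=float).ravel()
        self.dihedral_phi0 = np.asarray(self.dihedral_phi0, dtype=float).ravel()
        self.contact_sigma = np.asarray(self.contact_sigma, dtype=float).ravel()
        if np.any(self.bond_r0 <= 0) or np.any(self.contact_sigma <= 0):
            raise ValueError("reference distances must be positive")


def _angle(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Angles (rad) for index triples, vectorized."""
    a = x[idx[:, 0]] - x[idx[:, 1]]
    b = x[idx[:, 2]] - x[idx[:, 1]]
    cosang = np.sum(a * b, axis=1) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedral(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed torsion angles (rad) for index quadruples, vectorized."""
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    yv = np.sum(np.cross(n1, n2) * b2n, axis=1)
    xv = np.sum(n1 * n2, axis=1)
    return np.arctan2(yv, xv)


def build_ca_go(
    native: AtomicModel,
    cutoff: float | None = None,
    min_seq_sep: int | None = None,
    params: GoParams | None = None,
) -> GoTopology:
    """Construct the Cα Gō topology from a native (CA-only) model.

    Bonds/angles/dihedrals are laid over consecutive residues within
    each chain; native contacts are pairs at least ``min_seq_sep`` apart
    in sequence whose native distance is within ``cutoff``, with σij set
    to the native distance.  Consecutive residues farther apart than
    4.5 Å are treated as a chain break (warning, no bond).
    """
    params = params or GoParams()
    if cutoff is not None:
        params.cutoff = float(cutoff)
    if min_seq_sep is not None:
        params.min_seq_sep = int(min_seq_sep)
    if params.cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if params.min_seq_sep < 3:
        raise ValueError("min_seq_sep must be ≥ 3")
    if not all(str(a).strip() == "CA" for a in native.atom_name):
        raise ValueError("native model must be CA-only (run extract_ca first)")
    n = native.n_atoms
    if n < 2:
        raise ValueError("need at least 2 residues to build a topology")
    x = native.coords

    # consecutive connectivity within chains, broken at long bonds
    bonded_next = np.zeros(n - 1, dtype=bool)
    for i in range(n - 1):
        if native.chain_id[i] != native.chain_id[i + 1]:
            continue
        d = float(np.linalg.norm(x[i + 1] - x[i]))
        if d > CHAIN_BREAK_DISTANCE:
            logger.warning(
                "chain break between residues %d and %d (%.2f Å); no bond",
                int(native.residue_index[i]), int(native.residue_index[i + 1]), d,
            )
            continue
        bonded_next[i] = True

    bonds = np.array([[i, i + 1] for i in range(n - 1) if bonded_next[i]], int)
    angles = np.array(
        [[i, i + 1, i + 2] for i in range(n - 2)
         if bonded_next[i] and bonded_next[i + 1]], int)
    dihedrals = np.array(
        [[i, i + 1, i + 2, i + 3] for i in range(n - 3)
         if bonded_next[i] and bonded_next[i + 1] and bonded_next[i + 2]], int)

    bond_r0 = (np.linalg.norm(x[bonds[:, 1]] - x[bonds[:, 0]], axis=1)
               if len(bonds) else np.zeros(0))
    angle_theta0 = _angle(x, angles) if len(angles) else np.zeros(0)
    dihedral_phi0 = _dihedral(x, dihedrals) if len(dihedrals) else np.zeros(0)

    # native contacts and excluded-volume pairs over sequence-separated pairs
    ii, jj = np.triu_indices(n, k=1)
    seq_sep = jj - ii
    same_chain = native.chain_id[ii] == native.chain_id[jj]
    dist = np.linalg.norm(x[jj] - x[ii], axis=1)
    eligible = (~same_chain) | (seq_sep >= params.min_seq_sep)
    is_contact = eligible & (dist <= params.cutoff)
    contacts = np.column_stack([ii[is_contact], jj[is_contact]])
    contact_sigma = dist[is_contact]
    is_excl = ((~same_chain) | (seq_sep >= 3)) & ~is_contact
    excluded = np.column_stack([ii[is_excl], jj[is_excl]])

    return GoTopology(
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_theta0=angle_theta0,
        dihedrals=dihedrals, dihedral_phi0=dihedral_phi0,
        contacts=contacts, contact_sigma=contact_sigma,
        excluded=excluded, params=params, n_atoms=n,
    )


def _pair_accumulate(forces, idx, pair_force_over_r, dvec):
    """Add radial pair forces; pair_force_over_r is (−dE/dr)/r per pair."""
    f = pair_force_over_r[:, None] * dvec
    np.add.at(forces, idx[:, 1], f)
    np.add.at(forces, idx[:, 0], -f)


def go_energy_forces(
    top: GoTopology, coords: np.ndarray
) -> tuple[EnergyReport, np.ndarray]:
    """Energy report and analytic forces for the Gō potential.

    Raises ``ValueError`` when any interacting pair overlaps
    (separation < 1e-6 Å).
    """
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    if x.shape[0] != top.n_atoms:
        raise ValueError("coordinate count does not match topology")
    p = top.params
    report = EnergyReport()
    forces = np.zeros_like(x)

    if len(top.bonds):
        d = x[top.bonds[:, 1]] - x[top.bonds[:, 0]]
        r = np.linalg.norm(d, axis=1)
        _check_overlap(r, "bond")
        dr = r - top.bond_r0
        report.bond = float(np.sum(p.k_bond * dr**2))
        _pair_accumulate(forces, top.bonds, -2.0 * p.k_bond * dr / r, d)

    if len(top.angles):
        i, j, k = top.angles[:, 0], top.angles[:, 1], top.angles[:, 2]
        a = x[i] - x[j]
        b = x[k] - x[j]
        ra = np.linalg.norm(a, axis=1)
        rb = np.linalg.norm(b, axis=1)
        _check_overlap(ra, "angle")
        _check_overlap(rb, "angle")
        cosang = np.clip(np.sum(a * b, axis=1) / (ra * rb), -1.0, 1.0)
        theta = np.arccos(cosang)
        dth = theta - top.angle_theta0
        report.angle = float(np.sum(p.k_angle * dth**2))
        # dθ/da = −(b̂ − cosθ â)/(|a| sinθ); guard sinθ → 0
        sin = np.sqrt(np.maximum(1.0 - cosang**2, 1e-12))
        ahat = a / ra[:, None]
        bhat = b / rb[:, None]
        dth_da = -(bhat - cosang[:, None] * ahat) / (ra * sin)[:, None]
        dth_db = -(ahat - cosang[:, None] * bhat) / (rb * sin)[:, None]
        dEdth = (2.0 * p.k_angle * dth)[:, None]
        np.add.at(forces, i, -dEdth * dth_da)
        np.add.at(forces, k, -dEdth * dth_db)
        np.add.at(forces, j, dEdth * (dth_da + dth_db))

    if len(top.dihedrals):
        idx = top.dihedrals
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        rb2 = np.linalg.norm(b2, axis=1)
        _check_overlap(rb2, "dihedral")
        n1sq = np.sum(n1 * n1, axis=1)
        n2sq = np.sum(n2 * n2, axis=1)
        phi = _dihedral(x, idx)
        dphi = phi - top.dihedral_phi0
        report.dihedral = float(np.sum(
            p.k_dihedral1 * (1.0 - np.cos(dphi))
            + p.k_dihedral3 * (1.0 - np.cos(3.0 * dphi))
        ))
        dEdphi = (p.k_dihedral1 * np.sin(dphi)
                  + 3.0 * p.k_dihedral3 * np.sin(3.0 * dphi))
        # exact torsion gradient (standard MD formulation)
        dphi_d1 = -(rb2 / np.maximum(n1sq, 1e-12))[:, None] * n1
        dphi_d4 = (rb2 / np.maximum(n2sq, 1e-12))[:, None] * n2
        s12 = (np.sum(b1 * b2, axis=1) / rb2**2)[:, None]
        s32 = (np.sum(b3 * b2, axis=1) / rb2**2)[:, None]
        dphi_d2 = -(1.0 + s12) * dphi_d1 + s32 * dphi_d4
        dphi_d3 = s12 * dphi_d1 - (1.0 + s32) * dphi_d4
        g = dEdphi[:, None]
        np.add.at(forces, idx[:, 0], -g * dphi_d1)
        np.add.at(forces, idx[:, 1], -g * dphi_d2)
        np.add.at(forces, idx[:, 2], -g * dphi_d3)
        np.add.at(forces, idx[:, 3], -g * dphi_d4)

    if len(top.contacts):
        d = x[top.contacts[:, 1]] - x[top.contacts[:, 0]]
        r = np.linalg.norm(d, axis=1)
        _check_overlap(r, "contact")
        s10 = (top.contact_sigma / r) ** 10
        s12 = (top.contact_sigma / r) ** 12
        report.contact = float(np.sum(p.eps_contact * (5.0 * s12 - 6.0 * s10)))
        dEdr = p.eps_contact * 60.0 * (s10 - s12) / r
        _pair_accumulate(forces, top.contacts, -dEdr / r, d)

    if len(top.excluded):
        d = x[top.excluded[:, 1]] - x[top.excluded[:, 0]]
        r = np.linalg.norm(d, axis=1)
        _check_overlap(r, "excluded-volume")
        inside = r < p.r_excl
        if np.any(inside):
            ri = r[inside]
            s6 = (p.r_excl / ri) ** 6
            report.excluded = float(np.sum(p.eps_excl * (s6 - 1.0) ** 2))
            dEdr = np.zeros_like(r)
            dEdr[inside] = -12.0 * p.eps_excl * s6 * (s6 - 1.0) / ri
            _pair_accumulate(forces, top.excluded, -dEdr / r, d)

    return report, forces


def _check_overlap(r: np.ndarray, term: str) -> None:
    if np.any(r < 1e-6):
        raise ValueError(f"overlapping atoms in {term} term (r < 1e-6 Å)")


def write_topology(top: GoTopology, path: str | Path) -> None:
    """Serialize a topology to a plain-text sectioned table."""
    p = top.params
    with open(path, "w") as fh:
        fh.write(f"[params] n_atoms={top.n_atoms} k_bond={p.k_bond} "
                 f"k_angle={p.k_angle} k_dihedral1={p.k_dihedral1} "
                 f"k_dihedral3={p.k_dihedral3} eps_contact={p.eps_contact} "
                 f"eps_excl={p.eps_excl} r_excl={p.r_excl} "
                 f"cutoff={p.cutoff} min_seq_sep={p.min_seq_sep}\n")
        fh.write("[bonds] i j r0\n")
        for (i, j), r0 in zip(top.bonds, top.bond_r0):
            fh.write(f"{i} {j} {r0:.6f}\n")
        fh.write("[angles] i j k theta0\n")
        for (i, j, k), t0 in zip(top.angles, top.angle_theta0):
            fh.write(f"{i} {j} {k} {t0:.6f}\n")
        fh.write("[dihedrals] i j k l phi0\n")
        for (i, j, k, l), f0 in zip(top.dihedrals, top.dihedral_phi0):
            fh.write(f"{i} {j} {k} {l} {f0:.6f}\n")
        fh.write("[contacts] i j sigma\n")
        for (i, j), s in zip(top.contacts, top.contact_sigma):
            fh.write(f"{i} {j} {s:.6f}\n")
        fh.write("[excluded] i j\n")
        for i, j in top.excluded:
            fh.write(f"{i} {j}\n")


def read_topology(path: str | Path) -> GoTopology:
    """Read a topology written by :func:`write_topology`."""
    sections: dict[str, list[list[float]]] = {}
    header: dict[str, float] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("[params]"):
                for kv in line.split()[1:]:
                    k, v = kv.split("=")
                    header[k] = float(v)
                continue
            if line.startswith("["):
                current = line.split("]")[0][1:]
                sections[current] = []
                continue
            sections[current].append([float(t) for t in line.split()])

    def cols(name, n_idx, n_val):
        rows = sections.get(name, [])
        if not rows:
            return (np.zeros((0, n_idx), int),) + tuple(
                np.zeros(0) for _ in range(n_val))
        arr = np.asarray(rows)
        out = (arr[:, :n_idx].astype(int),)
        for c in range(n_val):
            out += (arr[:, n_idx + c],)
        return out

    bonds, bond_r0 = cols("bonds", 2, 1)
    angles, angle_theta0 = cols("angles", 3, 1)
    dihedrals, dihedral_phi0 = cols("dihedrals", 4, 1)
    contacts, contact_sigma = cols("contacts", 2, 1)
    (excluded,) = cols("excluded", 2, 0)
    params = GoParams(
        k_bond=header["k_bond"], k_angle=header["k_angle"],
        k_dihedral1=header["k_dihedral1"], k_dihedral3=header["k_dihedral3"],
        eps_contact=header["eps_contact"], eps_excl=header["eps_excl"],
        r_excl=header["r_excl"], cutoff=header["cutoff"],
        min_seq_sep=int(header["min_seq_sep"]),
    )
    return GoTopology(
        bonds=bonds, bond_r0=bond_r0, angles=angles,
        angle_theta0=angle_theta0, dihedrals=dihedrals,
        dihedral_phi0=dihedral_phi0, contacts=contacts,
        contact_sigma=contact_sigma, excluded=excluded,
        params=params, n_atoms=int(header["n_atoms"]),
    )
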