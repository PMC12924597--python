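"""Protein structure I/O and native-vs-modified comparison geometry.

Implements the structural side of the citrullination analysis: fixed-width
PDB reading/writing, Kabsch least-squares superposition, global and
per-residue RMSD, B-factor comparison, backbone (phi, psi) torsions,
angle-based secondary-structure assignment, polar-contact detection, and a
composite native-vs-modified comparison report.

Citrulline residues appear as the nonstandard residue name ``CIR``; they are
ordinary residues to every operation here.  B-factors are compared as
stored — for predicted models that column typically holds a per-residue
confidence rather than a crystallographic temperature factor, so the report
labels it neutrally as ``b_factor``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

PEPTIDE_BOND_BREAK = 2.5  # Å; a longer C(i-1)–N(i) distance means a chain break

# angle-based secondary-structure windows (degrees); chosen to capture ideal
# alpha (-57, -47) and beta (-120, +130) geometry with generous margins
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
SHEET_PHI = (-180.0, -90.0)
SHEET_PSI_HI = (90.0, 180.0)
SHEET_PSI_LO = (-180.0, -170.0)
MIN_HELIX_RUN = 4
MIN_SHEET_RUN = 3


@dataclass
class Atom:
    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0
    record: str = "ATOM"

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.name)

    @property
    def element(self) -> str:
        """Element inferred from the atom name (first alphabetic character)."""
        for c in self.name:
            if c.isalpha():
                return c.upper()
        return "?"


@dataclass
class Structure:
    """Ordered atom list; single model."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom key {dup}")
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinate in atom {a.key}")

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        return list(dict.fromkeys(a.chain for a in self.atoms))

    def residues(self) -> list[tuple[str, int]]:
        """(chain, resseq) pairs in order of first appearance."""
        return list(dict.fromkeys((a.chain, a.resseq) for a in self.atoms))

    def residue_atoms(self, chain: str, resseq: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain and a.resseq == resseq]

    def residue_name(self, chain: str, resseq: int) -> str:
        for a in self.atoms:
            if a.chain == chain and a.resseq == resseq:
                return a.resname
        raise KeyError(f"residue {chain}{resseq} not found")

    def get_atom(self, chain: str, resseq: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain == chain and a.resseq == resseq and a.name == name:
                return a
        raise KeyError(f"atom {(chain, resseq, name)} not found")

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new = [replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
               for a, p in zip(self.atoms, xyz)]
        return Structure(new)

    def copy(self) -> "Structure":
        return Structure([replace(a) for a in self.atoms])


# -- PDB fixed-width I/O ----------------------------------------------------

def _format_atom_name(name: str) -> str:
    # single-character elements start in column 14 (PDB v3.3 convention)
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write fixed-width PDB v3.3 ATOM/HETATM records (3-decimal coordinates)."""
    lines = []
    for a in s.atoms:
        rec = a.record if a.record in ("ATOM", "HETATM") else "ATOM"
        lines.append(
            f"{rec:<6s}{a.serial:>5d} {_format_atom_name(a.name)} "
            f"{a.resname:>3s} {a.chain:1s}{a.resseq:>4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(source: str | Path) -> Structure:
    """Parse ATOM/HETATM records from a PDB file (fixed columns)."""
    text = Path(source).read_text()
    atoms: list[Atom] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            atoms.append(Atom(
                serial=int(line[6:11]),
                name=line[12:16].strip(),
                resname=line[17:20].strip(),
                chain=line[21:22].strip() or "A",
                resseq=int(line[22:26]),
                x=float(line[30:38]),
                y=float(line[38:46]),
                z=float(line[46:54]),
                occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
                bfactor=float(line[60:66]) if line[60:66].strip() else 0.0,
                record=rec,
            ))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed PDB line {ln}: {line!r}") from exc
    return Structure(atoms)


# -- superposition ----------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3×3 proper rotation
    translation: np.ndarray    # applied after rotation
    global_rmsd: float
    transformed: Structure     # mobile with the transform applied to ALL atoms
    n_fitted: int


def _paired_coords(
    mobile: Structure,
    reference: Structure,
    atom_names: tuple[str, ...],
    residues: set[tuple[str, int]] | None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    ref_atoms = {a.key: a for a in reference.atoms}
    p, q, keys = [], [], []
    for a in mobile.atoms:
        if a.name not in atom_names:
            continue
        if residues is not None and (a.chain, a.resseq) not in residues:
            continue
        b = ref_atoms.get(a.key)
        if b is None:
            continue
        p.append(a.xyz)
        q.append(b.xyz)
        keys.append(a.key)
    return np.array(p), np.array(q), keys


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    atom_names: tuple[str, ...] = ("CA",),
    residues: set[tuple[str, int]] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by (chain, residue number, atom name) restricted to
    ``atom_names`` and optionally to a residue subset.  The rotation is
    constrained to be proper (no reflection).  The returned structure has the
    transform applied to every atom of ``mobile``.
    """
    p, q, keys = _paired_coords(mobile, reference, tuple(atom_names), residues)
    if len(p) < 3:
        raise ValueError(f"need >= 3 paired atoms, got {len(p)}")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = qc - r @ pc
    fitted = (r @ p.T).T + t
    rmsd = float(np.sqrt(((fitted - q) ** 2).sum(axis=1).mean()))
    moved = mobile.with_coords((r @ mobile.coords().T).T + t)
    return SuperpositionResult(rotation=r, translation=t, global_rmsd=rmsd,
                               transformed=moved, n_fitted=len(p))


def per_residue_rmsd(
    aligned_mobile: Structure,
    reference: Structure,
    atom_names: tuple[str, ...] = ("CA",),
) -> pd.DataFrame:
    """Per-residue RMSD over selected atoms of two already-superposed structures."""
    ref_atoms = {a.key: a for a in reference.atoms}
    rows = []
    for chain, resseq in aligned_mobile.residues():
        sq, n = 0.0, 0
        for a in aligned_mobile.residue_atoms(chain, resseq):
            if a.name not in atom_names:
                continue
            b = ref_atoms.get(a.key)
            if b is None:
                continue
            sq += float(((a.xyz - b.xyz) ** 2).sum())
            n += 1
        if n == 0:
            if (chain, resseq) not in {(c, r) for (c, r) in reference.residues()}:
                log.warning("residue %s%d absent from reference; skipped", chain, resseq)
            continue
        rows.append({"chain": chain, "resseq": resseq,
                     "resname": aligned_mobile.residue_name(chain, resseq),
                     "n_atoms": n, "rmsd": math.sqrt(sq / n)})
    return pd.DataFrame(rows)


def compare_bfactors(
    a: Structure,
    b: Structure,
    atom_names: tuple[str, ...] = ("CA",),
) -> pd.DataFrame:
    """Per-residue mean B-factor in each structure and their difference (a − b)."""
    rows = []
    b_atoms = {at.key: at for at in b.atoms}
    for chain, resseq in a.residues():
        ba, bb = [], []
        for at in a.residue_atoms(chain, resseq):
            if at.name not in atom_names:
                continue
            other = b_atoms.get(at.key)
            if other is None:
                continue
            ba.append(at.bfactor)
            bb.append(other.bfactor)
        if not ba:
            continue
        ma, mb = float(np.mean(ba)), float(np.mean(bb))
        rows.append({"chain": chain, "resseq": resseq,
                     "b_a": ma, "b_b": mb, "delta": ma - mb})
    return pd.DataFrame(rows)


# -- torsions and secondary structure --------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention, (−180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_torsions(s: Structure) -> pd.DataFrame:
    """Backbone phi/psi per residue (degrees); NaN where undefined.

    phi(i) = dihedral(C(i−1), N(i), CA(i), C(i));
    psi(i) = dihedral(N(i), CA(i), C(i), N(i+1)).
    A C(i−1)–N(i) distance above 2.5 Å is treated as a chain break.
    """
    rows = []
    residues = s.residues()
    bb: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for a in s.atoms:
        if a.name in ("N", "CA", "C"):
            bb.setdefault((a.chain, a.resseq), {})[a.name] = a.xyz
    for i, (chain, resseq) in enumerate(residues):
        cur = bb.get((chain, resseq), {})
        phi = psi = float("nan")
        prev = residues[i - 1] if i > 0 and residues[i - 1][0] == chain else None
        nxt = residues[i + 1] if i + 1 < len(residues) and residues[i + 1][0] == chain else None
        if prev is not None and {"N", "CA", "C"} <= cur.keys():
            pc = bb.get(prev, {}).get("C")
            if pc is not None and np.linalg.norm(cur["N"] - pc) <= PEPTIDE_BOND_BREAK:
                phi = dihedral(pc, cur["N"], cur["CA"], cur["C"])
        if nxt is not None and {"N", "CA", "C"} <= cur.keys():
            nn = bb.get(nxt, {}).get("N")
            if nn is not None and np.linalg.norm(nn - cur["C"]) <= PEPTIDE_BOND_BREAK:
                psi = dihedral(cur["N"], cur["CA"], cur["C"], nn)
        rows.append({"chain": chain, "resseq": resseq,
                     "resname": s.residue_name(chain, resseq), "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


def _in(v: float, lo: float, hi: float) -> bool:
    return lo <= v <= hi


def assign_ss_from_torsions(
    torsions: pd.DataFrame,
    min_helix_run: int = MIN_HELIX_RUN,
    min_sheet_run: int = MIN_SHEET_RUN,
) -> pd.DataFrame:
    """Assign H/E/C per residue from (phi, psi) windows with run-length demotion.

    Provisional H requires phi in [−100, −30] and psi in [−80, −5];
    provisional E requires phi in [−180, −90] and psi in [90, 180] or
    [−180, −170].  H runs shorter than ``min_helix_run`` and E runs shorter
    than ``min_sheet_run`` are demoted to coil.  Residues with undefined
    angles are coil.
    """
    out = torsions.copy()
    prov = []
    for _, r in out.iterrows():
        phi, psi = r["phi"], r["psi"]
        if math.isnan(phi) or math.isnan(psi):
            prov.append("C")
        elif _in(phi, *HELIX_PHI) and _in(psi, *HELIX_PSI):
            prov.append("H")
        elif _in(phi, *SHEET_PHI) and (_in(psi, *SHEET_PSI_HI) or _in(psi, *SHEET_PSI_LO)):
            prov.append("E")
        else:
            prov.append("C")
    # demote short runs, per chain
    ss = list(prov)
    chains = out["chain"].tolist()
    i = 0
    while i < len(ss):
        j = i
        while j < len(ss) and ss[j] == ss[i] and chains[j] == chains[i]:
            j += 1
        run = j - i
        if ss[i] == "H" and run < min_helix_run:
            ss[i:j] = ["C"] * run
        elif ss[i] == "E" and run < min_sheet_run:
            ss[i:j] = ["C"] * run
        i = j
    out["ss"] = ss
    return out[["chain", "resseq", "resname", "ss"]]


def ss_difference(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Per-residue secondary-structure change table and transition counts."""
    merged = a.merge(b, on=["chain", "resseq"], suffixes=("_a", "_b"))
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValueError("residue numbering mismatch between assignments")
    merged["changed"] = merged["ss_a"] != merged["ss_b"]
    counts = Counter(
        f"{ra}->{rb}" for ra, rb in zip(merged["ss_a"], merged["ss_b"]) if ra != rb
    )
    cols = ["chain", "resseq", "ss_a", "ss_b", "changed"]
    return merged[cols], counts


# -- contacts ---------------------------------------------------------------

@dataclass(frozen=True)
class Contact:
    chain_a: str
    resseq_a: int
    resname_a: str
    atom_a: str
    chain_b: str
    resseq_b: int
    resname_b: str
    atom_b: str
    distance: float

    @property
    def key(self) -> frozenset:
        """Distance-free identity of the contact, for gained/lost comparison."""
        return frozenset([(self.chain_a, self.resseq_a, self.atom_a),
                          (self.chain_b, self.resseq_b, self.atom_b)])


def polar_contacts(
    s: Structure,
    cutoff: float = 3.5,
    scope: str = "both",
) -> list[Contact]:
    """Heavy-atom polar contacts: N/O atom pairs from different residues ≤ cutoff Å.

    A distance criterion without angles approximates hydrogen bonding on
    hydrogen-free models.  Pairs within the same residue, and pairs between
    sequence-adjacent residues of the same chain (covalently linked through
    the backbone), are excluded.  ``scope`` restricts to intra-chain,
    inter-chain, or both.
    """
    if scope not in ("intra", "inter", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    polar = [a for a in s.atoms if a.element in ("N", "O")]
    if not polar:
        return []
    xyz = np.array([a.xyz for a in polar])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=cutoff)
    out = []
    for i, j in sorted(pairs):
        a, b = polar[i], polar[j]
        same_chain = a.chain == b.chain
        if same_chain and a.resseq == b.resseq:
            continue
        if same_chain and abs(a.resseq - b.resseq) == 1:
            continue
        if scope == "inter" and same_chain:
            continue
        if scope == "intra" and not same_chain:
            continue
        d = float(np.linalg.norm(a.xyz - b.xyz))
        first, second = ((a, b) if (a.chain, a.resseq, a.name) <= (b.chain, b.resseq, b.name)
                         else (b, a))
        out.append(Contact(first.chain, first.resseq, first.resname, first.name,
                           second.chain, second.resseq, second.resname, second.name, d))
    out.sort(key=lambda c: (c.chain_a, c.resseq_a, c.atom_a, c.chain_b, c.resseq_b, c.atom_b))
    return out


def residue_pair_distance(
    s: Structure,
    a: tuple[str, int, str],
    b: tuple[str, int, str],
) -> float:
    """Euclidean distance (Å) between two named atoms."""
    at = s.get_atom(*a)
    bt = s.get_atom(*b)
    return float(np.linalg.norm(at.xyz - bt.xyz))


# -- composite comparison ---------------------------------------------------

@dataclass
class StructureDeltaReport:
    superposition: SuperpositionResult
    per_residue: pd.DataFrame       # rmsd, b_factors, phi/psi and ss both, near_site
    ss_changes: Counter
    contacts_native: list[Contact]
    contacts_modified: list[Contact]
    contacts_gained: list[Contact]
    contacts_lost: list[Contact]
    site: int | None

    @property
    def global_rmsd(self) -> float:
        return self.superposition.global_rmsd


def compare_structures(
    native: Structure,
    modified: Structure,
    site: int | None = None,
    atom_names: tuple[str, ...] = ("CA",),
    contact_cutoff: float = 3.5,
    contact_scope: str = "both",
    site_window: int = 3,
) -> StructureDeltaReport:
    """Full native-vs-modified comparison.

    Superposes the modified structure onto the native one (CA fit by
    default), then reports global and per-residue RMSD, per-residue B-factor
    differences, torsions and secondary structure of both forms with their
    transitions, and polar contacts gained or lost in the modified form.
    Residues within ``site_window`` of ``site`` are flagged.
    """
    sup = kabsch_superpose(modified, native, atom_names=atom_names)
    aligned = sup.transformed
    rmsd_tab = per_residue_rmsd(aligned, native, atom_names=atom_names)
    btab = compare_bfactors(native, modified, atom_names=atom_names)

    tn = backbone_torsions(native)
    tm = backbone_torsions(aligned)
    ssn = assign_ss_from_torsions(tn)
    ssm = assign_ss_from_torsions(tm)
    ss_tab, ss_counts = ss_difference(ssn, ssm)
    ss_tab = ss_tab.rename(columns={"ss_a": "ss_native", "ss_b": "ss_modified"})

    per_res = rmsd_tab.merge(
        btab.rename(columns={"b_a": "b_factor_native", "b_b": "b_factor_modified",
                             "delta": "b_factor_delta"}),
        on=["chain", "resseq"], how="left")
    per_res = per_res.merge(
        tn.rename(columns={"phi": "phi_native", "psi": "psi_native"})[
            ["chain", "resseq", "phi_native", "psi_native"]],
        on=["chain", "resseq"], how="left")
    per_res = per_res.merge(
        tm.rename(columns={"phi": "phi_modified", "psi": "psi_modified"})[
            ["chain", "resseq", "phi_modified", "psi_modified"]],
        on=["chain", "resseq"], how="left")
    per_res = per_res.merge(ss_tab[["chain", "resseq", "ss_native", "ss_modified"]],
                            on=["chain", "resseq"], how="left")
    if site is not None:
        per_res["near_site"] = (per_res["resseq"] - site).abs() <= site_window
    else:
        per_res["near_site"] = False

    cn = polar_contacts(native, cutoff=contact_cutoff, scope=contact_scope)
    cm = polar_contacts(aligned, cutoff=contact_cutoff, scope=contact_scope)
    keys_n = {c.key for c in cn}
    keys_m = {c.key for c in cm}
    gained = [c for c in cm if c.key not in keys_n]
    lost = [c for c in cn if c.key not in keys_m]
    return StructureDeltaReport(
        superposition=sup, per_residue=per_res, ss_changes=ss_counts,
        contacts_native=cn, contacts_modified=cm,
        contacts_gained=gained, contacts_lost=lost, site=site,
    )
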