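"""Synthetic inputs with known ground truth for every pipeline stage.

No public dataset accompanies the serum citrullinome study, so this module
generates inputs that emulate its study conditions:

* LFQ-style protein × sample matrices (250 proteins, 10 case vs 10 control
  by default) with planted correlated modules, group-specific abundance
  shifts, and intensity-dependent (missing-not-at-random) missingness;
* toy backbone structures (helix / strand / mixed) built from ideal internal
  coordinates, locally perturbed "modified" copies, and ring multimers that
  mimic a pore-forming multimer;
* tiled-peptide binding signals with planted citrulline-specific epitopes.

Every generator is deterministic under a fixed seed, so all downstream
stages can be tested against the planted truth without any downloads.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .proteome_core import AbundanceTable
from .peptide_tiling import TileSet
from .structure import Atom, Structure

log = logging.getLogger(__name__)

# ideal backbone internal coordinates (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5
OMEGA = 180.0

IDEAL_ANGLES = {"helix": (-57.0, -47.0), "strand": (-120.0, 130.0)}

CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# --------------------------------------------------------------------------
# LFQ matrix simulation
# --------------------------------------------------------------------------

@dataclass
class LfqSimConfig:
    """Conditions for the simulated LFQ experiment.

    Defaults mirror the profiled cohort: 250 detected proteins, 10 case vs
    10 control samples, 6 differential proteins at |log2FC| = 2 (one of them
    down-regulated), residual noise sd 0.5 on the log2 scale, and logistic
    intensity-dependent missingness.
    """

    n_proteins: int = 250
    n_per_group: int = 10
    module_sizes: tuple[int, ...] = (30, 20, 15)
    module_loading: float = 0.8
    n_de: int = 6
    n_de_down: int = 1
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    mnar_midpoint: float = 21.0
    mnar_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("module sizes exceed n_proteins")
        if self.n_de > self.n_proteins:
            raise ValueError("n_de exceeds n_proteins")
        if not 0 <= self.module_loading <= 1:
            raise ValueError("module_loading must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_de_down > self.n_de:
            raise ValueError("n_de_down exceeds n_de")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated LFQ dataset."""

    de_effects: dict[str, float]          # protein id -> signed log2 effect
    module_membership: dict[str, int]     # protein id -> module index
    true_matrix: pd.DataFrame             # complete log2 abundances

    @property
    def de_proteins(self) -> set[str]:
        return set(self.de_effects)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_effects": self.de_effects,
            "module_membership": self.module_membership,
            "true_matrix": {
                "index": list(self.true_matrix.index),
                "columns": list(self.true_matrix.columns),
                "values": self.true_matrix.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        tm = pd.DataFrame(d["true_matrix"]["values"],
                          index=d["true_matrix"]["index"],
                          columns=d["true_matrix"]["columns"])
        return cls(de_effects={k: float(v) for k, v in d["de_effects"].items()},
                   module_membership={k: int(v) for k, v in d["module_membership"].items()},
                   true_matrix=tm)


def gen_lfq_dataset(config: LfqSimConfig) -> tuple[AbundanceTable, SimTruth]:
    """Simulate an LFQ abundance table with planted modules, DE and MNAR holes.

    log2 intensity = protein baseline + module latent factor × loading
    + group effect (differential proteins, case samples only) + iid noise;
    each cell is then masked missing with probability
    sigmoid(−mnar_slope × (x − mnar_midpoint)), so low-intensity cells drop
    out more often.  The emitted table holds raw intensities (2^x).
    """
    c = config
    rng = np.random.default_rng(c.seed)
    width = max(4, len(str(c.n_proteins)))
    proteins = [f"P{i + 1:0{width}d}" for i in range(c.n_proteins)]
    samples = ([f"case_{i + 1:02d}" for i in range(c.n_per_group)]
               + [f"control_{i + 1:02d}" for i in range(c.n_per_group)])
    groups = pd.Series(["case"] * c.n_per_group + ["control"] * c.n_per_group,
                       index=samples)
    n_s = 2 * c.n_per_group

    baseline = rng.normal(c.baseline_log2_mean, c.baseline_log2_sd, size=c.n_proteins)
    x = baseline[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_proteins, n_s))

    # planted correlated modules: shared latent factor per module and sample
    perm = rng.permutation(c.n_proteins)
    module_membership: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(c.module_sizes):
        members = perm[pos:pos + size]
        pos += size
        factor = rng.normal(0.0, 1.0, size=n_s)
        x[members] += c.module_loading * factor[None, :]
        for i in members:
            module_membership[proteins[i]] = m

    # planted differential proteins, drawn outside the modules so the two
    # kinds of planted structure stay separable, and from the quantifiable
    # abundance range: a protein sitting at the detection limit loses one
    # whole group to missingness, which is not the effect being planted
    free = [i for i in range(c.n_proteins) if proteins[i] not in module_membership]
    quantifiable = [i for i in free
                    if baseline[i] >= c.mnar_midpoint + 2.0 + abs(c.de_log2fc)]
    pool = quantifiable if len(quantifiable) >= c.n_de else free
    if len(pool) < c.n_de:
        raise ValueError("not enough non-module proteins to plant DE effects")
    de_idx = rng.choice(np.array(pool), size=c.n_de, replace=False)
    de_effects: dict[str, float] = {}
    for j, i in enumerate(de_idx):
        eff = -c.de_log2fc if j < c.n_de_down else c.de_log2fc
        x[i, :c.n_per_group] += eff
        de_effects[proteins[i]] = eff

    true = pd.DataFrame(x, index=proteins, columns=samples)
    p_miss = expit(-c.mnar_slope * (x - c.mnar_midpoint))
    mask = rng.random(size=x.shape) < p_miss
    values = pd.DataFrame(np.where(mask, np.nan, np.exp2(x)),
                          index=proteins, columns=samples)
    table = AbundanceTable(values, groups)
    return table, SimTruth(de_effects=de_effects,
                           module_membership=module_membership, true_matrix=true)


# --------------------------------------------------------------------------
# toy structures
# --------------------------------------------------------------------------

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: new atom d with |cd| = bond,
    angle(b, c, d) = angle and dihedral(a, b, c, d) = torsion."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _phi_psi_for(kind: str, n_res: int) -> list[tuple[float, float]]:
    if kind in IDEAL_ANGLES:
        return [IDEAL_ANGLES[kind]] * n_res
    if kind == "mixed":
        half = n_res // 2
        return ([IDEAL_ANGLES["helix"]] * half
                + [IDEAL_ANGLES["strand"]] * (n_res - half))
    raise ValueError(f"unknown structure kind {kind!r}")


def gen_toy_structure(kind: str, n_res: int, seed: int = 0,
                      chain: str = "A", resname: str = "ALA",
                      with_cb: bool = True) -> Structure:
    """Ideal backbone (N, CA, C, O, optionally CB) built by chain extension.

    Bond lengths/angles are fixed at ideal values; only (phi, psi) vary by
    ``kind``: helix (−57, −47), strand (−120, 130), or mixed (helix half
    followed by strand half).  B-factors are seeded uniform per residue.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues for defined torsions")
    angles = _phi_psi_for(kind, n_res)
    rng = np.random.default_rng(seed)
    bfac = rng.uniform(20.0, 80.0, size=n_res)

    ncac: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    th = math.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([math.cos(th), math.sin(th), 0.0])
    ncac.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = ncac[i - 1]
        psi_prev = angles[i - 1][1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, angles[i][0])
        ncac.append({"N": n_i, "CA": ca_i, "C": c_i})

    atoms: list[Atom] = []
    serial = 1
    for i, r in enumerate(ncac):
        psi_i = angles[i][1]
        o_i = _place(r["N"], r["CA"], r["C"], BOND_C_O, ANGLE_CA_C_O,
                     ((psi_i + 180.0 + 180.0) % 360.0) - 180.0)
        names = [("N", r["N"]), ("CA", r["CA"]), ("C", r["C"]), ("O", o_i)]
        if with_cb:
            cb = _place(r["C"], r["N"], r["CA"], BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
            names.append(("CB", cb))
        for name, xyz in names:
            atoms.append(Atom(serial=serial, name=name, resname=resname,
                              chain=chain, resseq=i + 1,
                              x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
                              occupancy=1.0, bfactor=float(round(bfac[i], 2))))
            serial += 1
    return Structure(atoms)


def add_polar_pseudo_atom(s: Structure, chain: str, resseq: int,
                          name: str, xyz: np.ndarray) -> Structure:
    """Append a named polar pseudo-atom (e.g. a side-chain oxygen stand-in).

    Used to engineer polar contacts in toy fixtures; the backbone builder
    carries no full side chains.
    """
    new = s.copy()
    resname = new.residue_name(chain, resseq)
    serial = max(a.serial for a in new.atoms) + 1
    new.atoms.append(Atom(serial=serial, name=name, resname=resname,
                          chain=chain, resseq=resseq,
                          x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2])))
    return Structure(new.atoms)


def perturb_structure(s: Structure, site: int, magnitude: float,
                      rename_to: str = "CIR", seed: int = 0,
                      window: int = 3, chain: str | None = None) -> Structure:
    """Locally displaced copy of ``s`` emulating a modification-induced shift.

    Residues within ±``window`` of ``site`` are displaced along a seeded
    random direction with a linearly decaying weight (maximum ``magnitude``
    at the site, zero beyond window+1); the site residue is renamed (e.g.
    ARG → CIR).  All other atoms are bit-identical to the input.
    """
    if chain is None:
        chain = s.chains()[0]
    if (chain, site) not in s.residues():
        raise ValueError(f"residue {chain}{site} not present")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u = u / np.linalg.norm(u)
    atoms = []
    for a in s.atoms:
        new = replace(a)
        if a.chain == chain:
            d = abs(a.resseq - site)
            if d <= window and magnitude != 0.0:
                w = magnitude * (1.0 - d / (window + 1.0))
                new.x += w * u[0]
                new.y += w * u[1]
                new.z += w * u[2]
            if a.resseq == site:
                new.resname = rename_to
        atoms.append(new)
    return Structure(atoms)


def gen_ring_multimer(s: Structure, n_copies: int, radius: float) -> Structure:
    """Ring of rigid copies of a single-chain structure about the z axis.

    Copy j is the input chain re-centred at distance ``radius`` from the
    axis and rotated by 2πj/n; chains are labelled A, B, … in order.
    Intra-chain geometry is preserved exactly (rigid motion).
    """
    if n_copies < 2:
        raise ValueError("need at least 2 copies")
    if n_copies > len(CHAIN_ALPHABET):
        raise ValueError(f"n_copies exceeds chain-id alphabet ({len(CHAIN_ALPHABET)})")
    if len(s.chains()) != 1:
        raise ValueError("ring multimer expects a single-chain input")
    xyz = s.coords()
    local = xyz - xyz.mean(axis=0) + np.array([radius, 0.0, 0.0])
    atoms: list[Atom] = []
    serial = 1
    for j in range(n_copies):
        th = 2.0 * math.pi * j / n_copies
        rot = np.array([[math.cos(th), -math.sin(th), 0.0],
                        [math.sin(th), math.cos(th), 0.0],
                        [0.0, 0.0, 1.0]])
        placed = local @ rot.T
        for a, p in zip(s.atoms, placed):
            atoms.append(replace(a, serial=serial, chain=CHAIN_ALPHABET[j],
                                 x=float(p[0]), y=float(p[1]), z=float(p[2])))
            serial += 1
    return Structure(atoms)


# --------------------------------------------------------------------------
# tiled-array signals
# --------------------------------------------------------------------------

def gen_array_signals(
    tiles: TileSet,
    epitopes: list[int],
    effect: float,
    n_case: int = 12,
    n_control: int = 12,
    seed: int = 0,
    isotypes: tuple[str, ...] = ("IgG",),
    background_log_mean: float = 7.0,
    background_log_sd: float = 0.5,
) -> TileSet:
    """Attach log-normal binding signals with planted citrulline epitopes.

    Every tile gets an independent log-normal background per sample.
    Citrulline-variant tiles whose 12-mer window covers a planted epitope
    position have their case-sample signals multiplied by ``effect``; native
    and homocitrulline tiles are untouched (the planted reactivity is
    citrulline-specific).  Epitope positions should point at arginines of
    the source sequence.
    """
    if tiles.n_tiles == 0:
        raise ValueError("empty tile set")
    L = len(tiles.sequence)
    for pos in epitopes:
        if not 1 <= pos <= L:
            raise ValueError(f"epitope position {pos} outside sequence (L={L})")
        if tiles.sequence[pos - 1] != "R":
            log.warning("epitope position %d is %r, not arginine", pos,
                        tiles.sequence[pos - 1])
    rng = np.random.default_rng(seed)
    samples, group_col, iso_col = [], [], []
    for iso in isotypes:
        for i in range(n_case):
            samples.append(f"case_{i + 1:02d}_{iso}")
            group_col.append("case")
            iso_col.append(iso)
        for i in range(n_control):
            samples.append(f"control_{i + 1:02d}_{iso}")
            group_col.append("control")
            iso_col.append(iso)
    sample_map = pd.DataFrame({"group": group_col, "isotype": iso_col}, index=samples)

    sig = np.exp(rng.normal(background_log_mean, background_log_sd,
                            size=(tiles.n_tiles, len(samples))))
    is_case = np.array([g == "case" for g in group_col])
    for row, t in enumerate(tiles.tiles.itertuples()):
        if t.variant != "cit":
            continue
        covers = any(t.start <= pos <= t.start + tiles.window - 1 for pos in epitopes)
        if covers:
            sig[row, is_case] *= effect
    signals = pd.DataFrame(sig, index=tiles.tiles["tile_id"].values, columns=samples)
    return replace(tiles, signals=signals, sample_map=sample_map)
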