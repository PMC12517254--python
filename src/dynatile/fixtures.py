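"""Synthetic Cα structures with known ground truth.

These generators build idealized coarse-grained folds (helix, β-hairpin,
or a βαβ-like mixed fold) with cysteines at ferredoxin-style motif
positions, SG sulfurs 2.8 Å off the Cα, and optional irons placed at the
canonical 2.25 Å Fe-S bond distance, so every pipeline stage — including
the cysteine-iron geometry filter — can be exercised end to end without
downloading any structure.  An embedded fixture concatenates duplicate
copies of the domain joined by cysteine-free coil linkers, emulating a
polyferredoxin target; the planted residue ranges are returned as ground
truth.  Geometry is deliberately idealized: it only needs to drive the
elastic network and the distance filters, not to be foldable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .structure_io import CaStructure, FeSite

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3  # Å
STRAND_SPACING = 3.8  # Å between consecutive Cα in an extended strand
SG_OFFSET = 2.8  # Å from Cα to SG
FE_BOND = 2.25  # Å from SG to planted Fe (mid Fe-S bonding window)

_AA_POOL = list("ADEFGHIKLMNPQRSTVWY")  # no cysteine; Cys is planted explicitly


def default_cys_positions(domain_length: int) -> tuple[int, ...]:
    """Two CxxCxxC-style clusters, one per domain half (1-based, relative)."""
    if domain_length < 18:
        return (min(3, domain_length),)
    return (8, 11, 14, domain_length - 9, domain_length - 6, domain_length - 3)


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic structures."""

    domain_length: int = 40
    fold: str = "mixed"  # helix | hairpin | mixed
    n_copies: int = 2
    linker_length: int = 30
    plant_fe: bool = True
    noise_rmsd: float = 0.0
    seed: int = 0
    cys_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.domain_length < 6:
            raise ValueError("domain_length must be >= 6")
        if self.linker_length < 0 or self.noise_rmsd < 0:
            raise ValueError("linker_length and noise_rmsd must be >= 0")
        if self.fold not in {"helix", "hairpin", "mixed"}:
            raise ValueError(f"unknown fold {self.fold!r}")
        if self.cys_positions is None:
            self.cys_positions = default_cys_positions(self.domain_length)
        if any(not 1 <= p <= self.domain_length for p in self.cys_positions):
            raise ValueError("cys_positions must lie within the domain")


class EmbeddedFixture(NamedTuple):
    structure: CaStructure
    fe_sites: list[FeSite]
    ground_truth: list[tuple[int, int]]


def _helix_coords(n: int, start: np.ndarray | None = None) -> np.ndarray:
    t = np.arange(n)
    xyz = np.column_stack(
        [
            HELIX_RISE * t,
            HELIX_RADIUS * np.cos(HELIX_TWIST * t),
            HELIX_RADIUS * np.sin(HELIX_TWIST * t),
        ]
    )
    if start is not None:
        xyz += start - xyz[0]
    return xyz


def _hairpin_coords(n: int) -> np.ndarray:
    n1 = (n + 1) // 2
    n2 = n - n1
    zig = 0.5 * (-1.0) ** np.arange(n1)
    up = np.column_stack([STRAND_SPACING * np.arange(n1), np.zeros(n1), zig])
    zig2 = 0.5 * (-1.0) ** np.arange(n2)
    down = np.column_stack(
        [STRAND_SPACING * (n1 - 1 - np.arange(n2)) + STRAND_SPACING / 2.0,
         np.full(n2, 5.0), zig2]
    )
    return np.vstack([up, down])


def _mixed_coords(n: int) -> np.ndarray:
    """βαβ-like: strand, helix running back above it, strand on top."""
    n1 = max(4, n // 4)
    n3 = max(4, n // 4)
    n2 = n - n1 - n3
    zig = 0.4 * (-1.0) ** np.arange(n1)
    s1 = np.column_stack([STRAND_SPACING * np.arange(n1), np.zeros(n1), zig])
    t = np.arange(n2)
    helix = np.column_stack(
        [
            s1[-1, 0] - HELIX_RISE * t,
            5.5 + HELIX_RADIUS * np.cos(HELIX_TWIST * t),
            HELIX_RADIUS * np.sin(HELIX_TWIST * t),
        ]
    )
    zig3 = 0.4 * (-1.0) ** np.arange(n3)
    x0 = helix[-1, 0]
    s3 = np.column_stack([x0 + STRAND_SPACING * np.arange(n3), np.full(n3, 11.0), zig3])
    return np.vstack([s1, helix, s3])


_FOLD_BUILDERS = {"helix": _helix_coords, "hairpin": _hairpin_coords, "mixed": _mixed_coords}


def _outward_units(ca_xyz: np.ndarray) -> np.ndarray:
    centroid = ca_xyz.mean(axis=0)
    d = ca_xyz - centroid
    norms = np.linalg.norm(d, axis=1)
    d[norms < 1e-6] = np.array([0.0, 0.0, 1.0])
    norms = np.linalg.norm(d, axis=1)
    return d / norms[:, None]


def _domain_sequence(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    seq = [str(rng.choice(_AA_POOL)) for _ in range(spec.domain_length)]
    for p in spec.cys_positions:
        seq[p - 1] = "C"
    return seq


def _assemble(source_id: str, aa: list[str], ca: np.ndarray, cys_flags: np.ndarray) -> CaStructure:
    n = len(aa)
    sg = np.full((n, 3), np.nan)
    units = _outward_units(ca)
    for i in np.flatnonzero(cys_flags):
        sg[i] = ca[i] + SG_OFFSET * units[i]
    return CaStructure(
        source_id=source_id,
        chain_id=["A"] * n,
        seq_index=np.arange(1, n + 1),
        auth_resnum=np.arange(1, n + 1),
        icode=[""] * n,
        aa=aa,
        ca_xyz=ca,
        sg_xyz=sg,
    )


def plant_fe_sites(structure: CaStructure) -> list[FeSite]:
    """One Fe per cysteine SG, placed 2.25 Å along the outward SG direction."""
    sites: list[FeSite] = []
    for i in range(structure.n_residues):
        sg = structure.sg_xyz[i]
        if not np.all(np.isfinite(sg)):
            continue
        u = sg - structure.ca_xyz[i]
        u = u / np.linalg.norm(u)
        fe = sg + FE_BOND * u
        sites.append(FeSite(tuple(float(v) for v in fe), "SF4", f"A:{i + 1}:SF4"))
    return sites


def make_toy_domain(spec: FixtureSpec) -> tuple[CaStructure, list[FeSite]]:
    """Idealized single-domain Cα trace with planted Cys (and Fe if asked).

    Deterministic given ``spec.seed``; consecutive Cα spacing for the helix
    fold is ~3.8 Å by construction of the helical parameters.
    """
    rng = np.random.default_rng(spec.seed)
    ca = _FOLD_BUILDERS[spec.fold](spec.domain_length)
    aa = _domain_sequence(spec, rng)
    cys = np.zeros(spec.domain_length, dtype=bool)
    cys[[p - 1 for p in spec.cys_positions]] = True
    structure = _assemble(f"toy_{spec.fold}{spec.domain_length}", aa, ca.copy(), cys)
    fe_sites = plant_fe_sites(structure) if spec.plant_fe else []
    return structure, fe_sites


def perturb(structure: CaStructure, rmsd: float, seed: int | None = None) -> CaStructure:
    """I.i.d. Gaussian displacement of Cα and SG with expected coordinate
    RMSD equal to ``rmsd`` (per-axis σ = rmsd/√3).  rmsd 0 is the identity."""
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    out = CaStructure(
        source_id=structure.source_id,
        chain_id=list(structure.chain_id),
        seq_index=structure.seq_index.copy(),
        auth_resnum=structure.auth_resnum.copy(),
        icode=list(structure.icode),
        aa=list(structure.aa),
        ca_xyz=structure.ca_xyz.copy(),
        sg_xyz=structure.sg_xyz.copy(),
    )
    if rmsd == 0:
        return out
    rng = np.random.default_rng(seed)
    sigma = rmsd / np.sqrt(3.0)
    out.ca_xyz += rng.normal(0.0, sigma, out.ca_xyz.shape)
    out.sg_xyz += rng.normal(0.0, sigma, out.sg_xyz.shape)  # NaN rows stay NaN
    return out


def _linker_coords(
    a: np.ndarray, b: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Coil-like path of n residues strictly between anchors a and b."""
    t = np.arange(1, n + 1) / (n + 1)
    base = a[None, :] + t[:, None] * (b - a)[None, :]
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wobble = np.column_stack(
        [
            np.zeros(n),
            1.2 * np.sin(2 * np.pi * t * 1.5 + phase[0]),
            1.2 * np.sin(2 * np.pi * t * 2.0 + phase[1]),
        ]
    )
    return base + wobble + rng.normal(0.0, 0.15, size=(n, 3))


def make_embedded_fixture(spec: FixtureSpec) -> EmbeddedFixture:
    """Concatenate ``n_copies`` duplicates of the toy domain joined by
    cysteine-free coil linkers; returns the planted residue ranges.

    Coordinate noise (``noise_rmsd``) is applied to the chain first and the
    irons are planted afterwards at the fixed 2.25 Å Fe-S bond length from
    each final SG position, mirroring the chemically rigid Fe-S bond of
    real clusters.
    """
    if spec.n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(spec.seed)
    domain_ca = _FOLD_BUILDERS[spec.fold](spec.domain_length)
    domain_aa = _domain_sequence(spec, rng)
    cys_rel = np.zeros(spec.domain_length, dtype=bool)
    cys_rel[[p - 1 for p in spec.cys_positions]] = True

    span = 3.4 * (spec.linker_length + 1)  # sub-extended coil end-to-end span
    ca_parts: list[np.ndarray] = []
    aa: list[str] = []
    cys_flags: list[np.ndarray] = []
    truth: list[tuple[int, int]] = []
    cursor = 0
    for k in range(spec.n_copies):
        if k == 0:
            offset = np.zeros(3)
        else:
            prev_end = ca_parts[-1][-1]
            anchor = prev_end + np.array([span, 0.0, 0.0])
            link = _linker_coords(prev_end, anchor, spec.linker_length, rng)
            ca_parts.append(link)
            aa.extend(str(rng.choice(_AA_POOL)) for _ in range(spec.linker_length))
            cys_flags.append(np.zeros(spec.linker_length, dtype=bool))
            cursor += spec.linker_length
            offset = anchor - domain_ca[0]
        ca_parts.append(domain_ca + offset)
        aa.extend(domain_aa)
        cys_flags.append(cys_rel.copy())
        truth.append((cursor + 1, cursor + spec.domain_length))
        cursor += spec.domain_length

    structure = _assemble(
        f"embedded_{spec.fold}{spec.domain_length}x{spec.n_copies}",
        aa,
        np.vstack(ca_parts),
        np.concatenate(cys_flags),
    )
    if spec.noise_rmsd > 0:
        structure = perturb(structure, spec.noise_rmsd, seed=rng.integers(2**31))
    fe_sites = plant_fe_sites(structure) if spec.plant_fe else []
    return EmbeddedFixture(structure=structure, fe_sites=fe_sites, ground_truth=truth)
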