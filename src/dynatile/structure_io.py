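"""Read macromolecular structures into a coarse-grained Cα representation.

The pipeline consumes only three kinds of atoms: the main-chain Cα of every
polymer residue, the SG sulfur of cysteines (the first-shell iron ligand),
and the Fe atoms of iron-sulfur hetero-groups.  Everything else in a PDB or
mmCIF file is ignored.  Residues are renumbered 1..N consecutively over the
selected chains ("seq_index"); author numbering is kept alongside so results
can be mapped back onto the deposited structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import IUPACData, PDBData
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import EmptyModelError, FormatError

logger = logging.getLogger(__name__)

#: hetero-group residue names treated as iron-sulfur clusters by default
DEFAULT_FE_CLUSTER_NAMES = frozenset({"SF4", "FES", "F3S", "FE"})

_THREE_TO_ONE = {k.upper(): v for k, v in PDBData.protein_letters_3to1.items()}
_ONE_TO_THREE = {k: v.upper() for k, v in IUPACData.protein_letters_1to3.items()}


@dataclass
class CaStructure:
    """Coarse-grained structure: one Cα per residue, SG for cysteines.

    ``seq_index`` is 1-based and consecutive (1..N) over all retained
    residues; ``auth_resnum``/``chain_id``/``icode`` preserve the author
    numbering of the source file.  ``sg_xyz`` rows are NaN for residues
    that are not cysteines (or whose side chain is disordered/absent).
    """

    source_id: str
    chain_id: list[str]
    seq_index: np.ndarray
    auth_resnum: np.ndarray
    icode: list[str]
    aa: list[str]
    ca_xyz: np.ndarray
    sg_xyz: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.seq_index)

    @property
    def sequence(self) -> str:
        return "".join(self.aa)

    def validate(self) -> None:
        n = self.n_residues
        if n == 0:
            raise EmptyModelError(f"{self.source_id}: no residues")
        if not np.array_equal(self.seq_index, np.arange(1, n + 1)):
            raise ValueError("seq_index must be 1..N with no gaps")
        if self.ca_xyz.shape != (n, 3) or self.sg_xyz.shape != (n, 3):
            raise ValueError("coordinate arrays must be (N, 3)")
        if not np.all(np.isfinite(self.ca_xyz)):
            raise ValueError("non-finite Cα coordinates")
        for i, a in enumerate(self.aa):
            has_sg = bool(np.all(np.isfinite(self.sg_xyz[i])))
            if has_sg and a != "C":
                raise ValueError(f"residue {i + 1}: SG present but aa != C")

    def subsequence(self, start: int, end: int) -> str:
        """One-letter sequence for seq_index range [start, end] inclusive."""
        return "".join(self.aa[start - 1 : end])

    def to_pdb_text(self, fe_sites: Sequence["FeSite"] | None = None) -> str:
        """Serialize as a minimal standard PDB (Cα, Cys SG, Fe HETATMs)."""
        lines: list[str] = []
        serial = 1
        for i in range(self.n_residues):
            res3 = _ONE_TO_THREE.get(self.aa[i], "UNK")
            ch = (self.chain_id[i] or "A")[0]
            resnum = int(self.auth_resnum[i])
            icode = (self.icode[i] or " ")[0]
            x, y, z = self.ca_xyz[i]
            lines.append(
                f"ATOM  {serial:5d}  CA  {res3:<3s} {ch}{resnum:4d}{icode}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
            if np.all(np.isfinite(self.sg_xyz[i])):
                sx, sy, sz = self.sg_xyz[i]
                lines.append(
                    f"ATOM  {serial:5d}  SG  {res3:<3s} {ch}{resnum:4d}{icode}"
                    f"   {sx:8.3f}{sy:8.3f}{sz:8.3f}  1.00  0.00           S"
                )
                serial += 1
        for k, fe in enumerate(fe_sites or []):
            x, y, z = fe.fe_xyz
            lines.append(
                f"HETATM{serial:5d} FE   {fe.cluster_name:<3s} Z{k + 1:4d} "
                f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          FE"
            )
            serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write_pdb(self, path: str | Path, fe_sites: Sequence["FeSite"] | None = None) -> None:
        Path(path).write_text(self.to_pdb_text(fe_sites))


@dataclass(frozen=True)
class FeSite:
    """One iron atom of an iron-sulfur hetero-group."""

    fe_xyz: tuple[float, float, float]
    cluster_name: str
    cluster_id: str


@dataclass
class MatchRecord:
    """A converged tile match mapped back onto the target structure."""

    island_id: str
    tile_length: int
    tile_center: int
    residue_range: tuple[int, int]
    chain: str
    auth_range: tuple[int, int]
    scores: dict = field(default_factory=dict)
    converged: bool = True


def _get_parser(path: Path):
    if path.suffix.lower() in {".cif", ".mmcif"}:
        return MMCIFParser(QUIET=True)
    return PDBParser(QUIET=True)


def _pick_atom(residue, name: str):
    """Return the atom, resolving altlocs to highest occupancy, or None."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        atom = max(children, key=lambda a: a.get_occupancy() or 0.0)
    return atom


def load_structure(
    path: str | Path,
    chains: Iterable[str] | None = None,
    source_id: str | None = None,
) -> CaStructure:
    """Load the first model of a PDB/mmCIF file as a :class:`CaStructure`.

    Residues are kept if they carry a Cα atom and look peptide-like
    (hetero-residues such as MSE are accepted when they also have a
    backbone N; isolated metal ions named "CA" are not).  Residues without
    a Cα are skipped with a warning.  Insertion-coded residues are kept
    as distinct residues in file order.
    """
    path = Path(path)
    parser = _get_parser(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(parser.get_structure(path.stem, str(path)).get_models())
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"could not parse {path}: {exc}") from exc

    chain_filter = set(chains) if chains is not None else None
    chain_ids: list[str] = []
    auth: list[int] = []
    icodes: list[str] = []
    aas: list[str] = []
    cas: list[np.ndarray] = []
    sgs: list[np.ndarray] = []
    n_skipped = 0

    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        for residue in chain:
            hetflag, _, icode = residue.id
            if hetflag == "W":
                continue
            resname = residue.get_resname().strip().upper()
            ca = _pick_atom(residue, "CA")
            if ca is None or (hetflag != " " and _pick_atom(residue, "N") is None):
                if hetflag == " ":
                    n_skipped += 1
                continue
            chain_ids.append(chain.id)
            auth.append(int(residue.id[1]))
            icodes.append(icode.strip())
            aas.append(_THREE_TO_ONE.get(resname, "X"))
            cas.append(np.asarray(ca.get_coord(), dtype=float))
            if aas[-1] == "C":
                sg = _pick_atom(residue, "SG")
                sgs.append(
                    np.asarray(sg.get_coord(), dtype=float)
                    if sg is not None
                    else np.full(3, np.nan)
                )
            else:
                sgs.append(np.full(3, np.nan))

    if n_skipped:
        logger.warning("%s: skipped %d residues without a Cα", path.name, n_skipped)
    if not cas:
        raise EmptyModelError(f"{path}: no polymer residues with a Cα")

    structure = CaStructure(
        source_id=source_id or path.stem,
        chain_id=chain_ids,
        seq_index=np.arange(1, len(cas) + 1),
        auth_resnum=np.asarray(auth, dtype=int),
        icode=icodes,
        aa=aas,
        ca_xyz=np.vstack(cas),
        sg_xyz=np.vstack(sgs),
    )
    structure.validate()
    return structure


def extract_fe_sites(
    path: str | Path,
    cluster_names: Iterable[str] = DEFAULT_FE_CLUSTER_NAMES,
) -> list[FeSite]:
    """Extract Fe atoms of iron-sulfur hetero-groups (first model).

    Returns one :class:`FeSite` per iron atom in hetero-groups whose residue
    name is in ``cluster_names``; an empty list when the structure binds no
    such cluster.
    """
    path = Path(path)
    parser = _get_parser(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(parser.get_structure(path.stem, str(path)).get_models())
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse {path}: {exc}") from exc

    names = {n.strip().upper() for n in cluster_names}
    sites: list[FeSite] = []
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip().upper()
            if resname not in names:
                continue
            for atom in residue:
                element = (atom.element or "").strip().upper()
                if element == "FE" or atom.get_name().strip().upper().startswith("FE"):
                    xyz = tuple(float(v) for v in atom.get_coord())
                    cluster_id = f"{chain.id}:{residue.id[1]}:{resname}"
                    sites.append(FeSite(xyz, resname, cluster_id))
    return sites


_PYMOL_COLORS = [
    "red", "orange", "yellow", "green", "cyan", "blue", "purple",
    "magenta", "salmon", "teal", "olive", "slate",
]


def write_pymol_script(matches: Sequence[MatchRecord], path: str | Path) -> None:
    """Emit a PyMOL script highlighting every match, one color per island.

    The script selects by chain + author residue range, so it can be run
    directly on the deposited structure.  Re-running it is idempotent.
    An empty match list is a no-op (with a warning).
    """
    if not matches:
        logger.warning("write_pymol_script: no matches to write, skipping %s", path)
        return
    island_ids = sorted({m.island_id for m in matches})
    color_of = {isl: _PYMOL_COLORS[i % len(_PYMOL_COLORS)] for i, isl in enumerate(island_ids)}
    lines = ["bg_color white", "hide everything", "show cartoon", "color grey80"]
    for m in matches:
        sel = f"island_{m.island_id}"
        lo, hi = m.auth_range
        lines.append(f"select {sel}, (chain {m.chain} and resi {lo}-{hi})")
        lines.append(f"color {color_of[m.island_id]}, {sel}")
        lines.append(f"show cartoon, {sel}")
    lines.append("deselect")
    Path(path).write_text("\n".join(lines) + "\n")


def write_match_table(matches: Sequence[MatchRecord], path: str | Path) -> None:
    """Write the final match table as TSV with a documented header."""
    header = (
        "island_id\tlength\tcenter\tchain\tauth_start\tauth_end\t"
        "s_cosine\ts_frobenius\ts_sw\ts_weighted\tconverged"
    )
    rows = [header]
    for m in matches:
        s = m.scores
        rows.append(
            f"{m.island_id}\t{m.tile_length}\t{m.tile_center}\t{m.chain}\t"
            f"{m.auth_range[0]}\t{m.auth_range[1]}\t"
            f"{s.get('s_cosine', float('nan')):.6f}\t"
            f"{s.get('s_frobenius', float('nan')):.6f}\t"
            f"{s.get('s_sw', float('nan')):.4f}\t"
            f"{s.get('s_weighted', float('nan')):.6f}\t{int(m.converged)}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
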