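"""All-atom structure container, PDB input, property assignment, superposition.

A :class:`StructureModel` is a column-oriented record of protein atoms (one
numpy array per field) read from a PDB file.  :func:`assign_properties`
attaches the seven-channel boolean property flags and per-atom van der Waals
radii; :func:`mutation_center` locates the grid center of a mutation site
(side-chain beta carbon, alpha carbon for glycine); :func:`superpose` rigidly
fits a mutant model onto its wild-type reference with the Kabsch algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import chem
from .chem import N_CHANNELS, PropertyRuleSet

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into protein atoms."""


@dataclass
class StructureModel:
    """Ordered collection of protein atoms with optional property flags.

    Atoms keep file order; residues are identified by
    ``(chain_id, res_id, ins_code)`` in PDB author numbering.
    """

    serial: np.ndarray          # (n,) int
    atom_name: np.ndarray       # (n,) str
    element: np.ndarray         # (n,) str
    res_name: np.ndarray        # (n,) str, 3-letter code
    res_id: np.ndarray          # (n,) int, author numbering
    ins_code: np.ndarray        # (n,) str
    chain_id: np.ndarray        # (n,) str
    coord: np.ndarray           # (n, 3) float64, Angstrom
    vdw_radius: np.ndarray | None = None   # (n,) float, set by assign_properties
    flags: np.ndarray | None = None        # (n, 7) bool, set by assign_properties
    structure_id: str = ""
    _res_index: dict = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def copy(self) -> "StructureModel":
        return StructureModel(
            serial=self.serial.copy(),
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            res_name=self.res_name.copy(),
            res_id=self.res_id.copy(),
            ins_code=self.ins_code.copy(),
            chain_id=self.chain_id.copy(),
            coord=self.coord.copy(),
            vdw_radius=None if self.vdw_radius is None else self.vdw_radius.copy(),
            flags=None if self.flags is None else self.flags.copy(),
            structure_id=self.structure_id,
        )

    # -- residue bookkeeping -------------------------------------------------

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Residue identifiers ``(chain, res_id, ins_code)`` in file order."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def residue_mask(self, chain: str, res_id: int, ins_code: str = "") -> np.ndarray:
        return (
            (self.chain_id == chain)
            & (self.res_id == res_id)
            & (self.ins_code == ins_code)
        )

    def atom_coord(self, chain: str, res_id: int, atom_name: str,
                   ins_code: str = "") -> np.ndarray | None:
        mask = self.residue_mask(chain, res_id, ins_code) & (self.atom_name == atom_name)
        idx = np.flatnonzero(mask)
        return self.coord[idx[0]] if idx.size else None

    def chain_sequence(self, chain: str) -> str:
        """One-letter sequence of a chain; non-standard residues map to X."""
        letters = []
        for (c, r, i) in self.residue_keys():
            if c != chain:
                continue
            mask = self.residue_mask(c, r, i)
            res = str(self.res_name[np.flatnonzero(mask)[0]])
            letters.append(chem.AA_3TO1.get(res, "X"))
        if not letters:
            raise KeyError(f"chain {chain!r} not present in {self.structure_id or 'structure'}")
        return "".join(letters)

    def chains(self) -> list[str]:
        out: dict[str, None] = {}
        for c in self.chain_id:
            out.setdefault(str(c), None)
        return list(out)


def read_pdb(path, model_index: int = 1, structure_id: str | None = None) -> StructureModel:
    """Read the protein atoms of one model from a PDB file.

    Waters and non-protein heteroatoms are dropped.  Coordinates are kept
    exactly as written in the file.

    Parameters
    ----------
    path
        PDB file with at least one ATOM record.
    model_index
        1-based model number (for multi-MODEL files).
    """
    from biotite.structure import filter_amino_acids
    from biotite.structure.io.pdb import PDBFile

    path = str(path)
    try:
        pdb_file = PDBFile.read(path)
        atoms = pdb_file.get_structure(model=model_index)
    except Exception as exc:  # re-raise with file/line context
        line_no = _first_malformed_line(path)
        where = f"{path}:{line_no}" if line_no else path
        raise PDBParseError(f"cannot parse PDB file {where}: {exc}") from exc
    mask = filter_amino_acids(atoms)
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise PDBParseError(f"no protein atoms in {path} (model {model_index})")
    n = atoms.array_length()
    return StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=atoms.atom_name.astype("U6"),
        element=np.char.upper(atoms.element.astype("U4")),
        res_name=atoms.res_name.astype("U4"),
        res_id=atoms.res_id.astype(int),
        ins_code=atoms.ins_code.astype("U2")
        if "ins_code" in atoms.get_annotation_categories()
        else np.full(n, "", dtype="U2"),
        chain_id=atoms.chain_id.astype("U4"),
        coord=np.asarray(atoms.coord, dtype=np.float64),
        structure_id=structure_id if structure_id is not None else path,
    )


def _first_malformed_line(path: str) -> int | None:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                    return i
    except OSError:
        return None
    return None


def assign_properties(structure: StructureModel,
                      rules: PropertyRuleSet | None = None) -> StructureModel:
    """Attach the seven property flags and van der Waals radii to every atom.

    Channel order is :data:`voxstab.chem.CHANNEL_NAMES`.  Non-standard
    residues (and unknown atom names within standard residues) fall back to
    occupancy-only flags with a logged warning.  Idempotent.
    """
    if rules is None:
        rules = PropertyRuleSet()
    out = structure.copy()
    n = out.n_atoms
    flags = np.zeros((n, N_CHANNELS), dtype=bool)
    radii = np.empty(n, dtype=np.float64)
    HYDROPHOBIC, AROMATIC, DONOR, ACCEPTOR, POSITIVE, NEGATIVE, OCCUPANCY = range(7)

    flags[:, OCCUPANCY] = True
    for i in range(n):
        radii[i] = rules.radius_for(str(out.element[i]))

    positive_map = rules.positive_atoms
    warned_nonstd: set[str] = set()
    # chain termini for the ionizable N-terminal amine / C-terminal carboxylate
    res_keys = structure.residue_keys()
    first_res: dict[str, tuple] = {}
    last_res: dict[str, tuple] = {}
    for key in res_keys:
        first_res.setdefault(key[0], key)
        last_res[key[0]] = key

    # per-residue heavy-atom names for hydrogen-parent resolution
    for key in res_keys:
        mask = structure.residue_mask(*key)
        idx = np.flatnonzero(mask)
        res = str(out.res_name[idx[0]])
        standard = res in chem.STANDARD_AA
        if not standard and res not in warned_nonstd:
            warned_nonstd.add(res)
            logger.warning(
                "non-standard residue %s at %s:%s%s: occupancy-only flags",
                res, key[0], key[1], key[2],
            )
        heavy_names = [str(out.atom_name[j]) for j in idx if str(out.element[j]) != "H"]
        aromatic_set = chem.AROMATIC_RING_CARBONS.get(res, frozenset())
        non_hphob = chem.NON_HYDROPHOBIC_SIDECHAIN_C.get(res, frozenset())
        pos_set = positive_map.get(res, frozenset())
        neg_set = chem.NEGATIVE_ATOMS.get(res, frozenset())
        is_nterm = first_res.get(key[0]) == key
        is_cterm = last_res.get(key[0]) == key
        for j in idx:
            if not standard:
                continue
            name = str(out.atom_name[j])
            el = str(out.element[j])
            if el == "C":
                flags[j, AROMATIC] = name in aromatic_set
                flags[j, HYDROPHOBIC] = flags[j, AROMATIC] or (
                    name != "C" and name not in non_hphob
                )
            elif el in ("N", "O", "S"):
                flags[j, DONOR] = True
                if name in pos_set or (is_nterm and name == "N"):
                    flags[j, POSITIVE] = True
                if name in neg_set or (is_cterm and name in ("OXT", "O")):
                    flags[j, NEGATIVE] = True
            elif el == "H":
                parent = chem.hydrogen_parent(name, heavy_names)
                if parent is None:
                    logger.warning("cannot resolve parent of hydrogen %s in %s", name, res)
                else:
                    p_el = parent[0]  # first letter of a heavy-atom PDB name
                    flags[j, ACCEPTOR] = p_el in ("N", "O", "S")

    if not np.any(out.element == "H"):
        logger.warning(
            "structure %s has no hydrogens; the polar-hydrogen channel is empty",
            out.structure_id or "<unnamed>",
        )
    if rules.swap_donor_acceptor:
        flags[:, [DONOR, ACCEPTOR]] = flags[:, [ACCEPTOR, DONOR]]
    out.flags = flags
    out.vdw_radius = radii
    return out


def mutation_center(structure: StructureModel, chain: str, res_seq: int,
                    ins_code: str = "", fallback_to_ca: bool = False) -> np.ndarray:
    """Grid-center coordinates of a mutation site.

    Returns the C-beta coordinates of the residue, or C-alpha when the
    residue is glycine.  A non-glycine residue without C-beta is an error
    unless ``fallback_to_ca`` is set (the fallback is logged).
    """
    mask = structure.residue_mask(chain, res_seq, ins_code)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise KeyError(
            f"residue {chain}:{res_seq}{ins_code} not found in "
            f"{structure.structure_id or 'structure'}"
        )
    res = str(structure.res_name[idx[0]])
    target = "CA" if res == "GLY" else "CB"
    coord = structure.atom_coord(chain, res_seq, target, ins_code)
    if coord is None and target == "CB" and fallback_to_ca:
        logger.warning("residue %s %s:%s lacks CB; falling back to CA", res, chain, res_seq)
        coord = structure.atom_coord(chain, res_seq, "CA", ins_code)
    if coord is None:
        raise ValueError(f"residue {res} {chain}:{res_seq}{ins_code} lacks a {target} atom")
    return np.asarray(coord, dtype=np.float64)


def superpose(mobile: StructureModel, reference: StructureModel,
              exclude_site: tuple[str, int] | None = None,
              ) -> tuple[StructureModel, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (Kabsch).

    Anchors are the C-alpha atoms of residues common to both structures,
    excluding ``exclude_site`` (the mutated ``(chain, res_id)``).  The fit is
    a proper rotation plus translation (no reflection); the returned RMSD is
    computed over the anchors after transformation.
    """
    mob_keys = {k for k in mobile.residue_keys()}
    ref_keys = {k for k in reference.residue_keys()}
    common = sorted(mob_keys & ref_keys, key=lambda k: (k[0], k[1], k[2]))
    if exclude_site is not None:
        common = [k for k in common if (k[0], k[1]) != tuple(exclude_site)]
    mob_pts, ref_pts = [], []
    for key in common:
        a = mobile.atom_coord(key[0], key[1], "CA", key[2])
        b = reference.atom_coord(key[0], key[1], "CA", key[2])
        if a is not None and b is not None:
            mob_pts.append(a)
            ref_pts.append(b)
    if len(mob_pts) < 3:
        raise ValueError(
            f"superposition needs >= 3 common CA anchors, found {len(mob_pts)}"
        )
    mob_pts = np.asarray(mob_pts)
    ref_pts = np.asarray(ref_pts)
    mob_centroid = mob_pts.mean(axis=0)
    ref_centroid = ref_pts.mean(axis=0)
    mob_c = mob_pts - mob_centroid
    ref_c = ref_pts - ref_centroid
    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        warnings.warn("anchor atoms are nearly collinear; rotation is ill-determined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on rank-deficient input
        rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = float(rssd / np.sqrt(len(mob_pts)))
    out = mobile.copy()
    out.coord = rot.apply(out.coord - mob_centroid) + ref_centroid
    return out, rmsd
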