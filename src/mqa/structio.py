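"""Structure and confidence I/O.

Reads and writes multichain protein structures in PDB format while keeping
the correspondence between the deposited sequence (SEQRES) and the
experimentally resolved residues (ATOM records).  Predicted models carry
per-residue pLDDT in the B-factor column; AlphaFold confidence JSON files
carry the PAE matrix and optionally pLDDT/pTM/ipTM.

All downstream scoring matches residues between a model and a reference
structure by SEQRES position, never by author numbering, so the
SEQRES-to-ATOM alignment built here is the backbone of the whole toolkit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
from Bio import Align
from Bio.Data.IUPACData import protein_letters_1to3

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "ConfidenceData",
    "StructureError",
    "read_structure",
    "write_structure",
    "align_seqres_to_atom",
    "read_confidence",
    "write_confidence",
    "common_residue_restriction",
]


class StructureError(ValueError):
    """Raised for unusable structure or confidence input."""


_THREE_FROM_ONE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
_ONE_FROM_THREE = {v: k for k, v in _THREE_FROM_ONE.items()}


def three_to_one(name: str) -> str:
    if name in _ONE_FROM_THREE:
        return _ONE_FROM_THREE[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    residue_index: int
    insertion_code: str
    chain_id: str
    coords: np.ndarray
    bfactor: float
    element: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if self.bfactor < 0:
            raise StructureError(f"negative B-factor for atom {self.name}")


@dataclass
class Residue:
    """One resolved residue: author numbering plus its atoms."""

    name: str                      # three-letter code
    residue_index: int             # author numbering
    insertion_code: str = ""
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)
    bfactors: Dict[str, float] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    @property
    def plddt(self) -> float:
        """Residue-level pLDDT read off the B-factor column (CA preferred)."""
        if "CA" in self.bfactors:
            return self.bfactors["CA"]
        return float(np.mean(list(self.bfactors.values())))

    def coord(self, atom_name: str) -> Optional[np.ndarray]:
        return self.atoms.get(atom_name)


@dataclass
class Chain:
    chain_id: str
    seqres: str
    residues: List[Residue]
    # 1-based SEQRES position -> 1-based resolved-residue position
    seqres_to_atom: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seqres_to_atom and self.seqres:
            self.seqres_to_atom = align_seqres_to_atom(self)

    @property
    def resolved_sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    @property
    def atom_to_seqres(self) -> Dict[int, int]:
        return {v: k for k, v in self.seqres_to_atom.items()}

    def residue_at_seqres(self, pos: int) -> Residue:
        return self.residues[self.seqres_to_atom[pos] - 1]

    @property
    def resolved_seqres_positions(self) -> List[int]:
        return sorted(self.seqres_to_atom)

    @property
    def seqres_atom_diff(self) -> int:
        return len(self.seqres) - len(self.residues)


@dataclass
class Structure:
    id: str
    chains: List[Chain]
    resolution: Optional[float] = None

    @property
    def chain_ids(self) -> List[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"chain {chain_id!r} not in structure {self.id!r}")

    @property
    def stoichiometry_class(self) -> str:
        seqs = {c.seqres for c in self.chains}
        return "homomer" if len(seqs) == 1 else "heteromer"

    @property
    def is_homomer(self) -> bool:
        return self.stoichiometry_class == "homomer"

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def residue_order(self) -> List[Tuple[str, int]]:
        """Chain-major (chain_id, author residue_index) order of resolved residues."""
        return [(c.chain_id, r.residue_index) for c in self.chains for r in c.residues]

    def global_index(self) -> Dict[Tuple[str, int], int]:
        """Map (chain_id, 1-based resolved position) -> global residue index."""
        out: Dict[Tuple[str, int], int] = {}
        i = 0
        for c in self.chains:
            for k in range(len(c.residues)):
                out[(c.chain_id, k + 1)] = i
                i += 1
        return out

    @property
    def seqres_atom_diff(self) -> int:
        return sum(c.seqres_atom_diff for c in self.chains)


@dataclass
class ConfidenceData:
    """Per-residue pLDDT and residue-pair PAE for one predicted complex.

    ``pae[i, j]`` is the predicted positional error (Å) of residue j when the
    model is aligned on residue i; the matrix is generally asymmetric.
    ``order`` is the chain-major (chain_id, author residue_index) order shared
    by ``plddt`` and both PAE axes.
    """

    plddt: np.ndarray
    pae: np.ndarray
    order: List[Tuple[str, int]]
    ptm: Optional[float] = None
    iptm: Optional[float] = None

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = len(self.plddt)
        if self.pae.shape != (n, n):
            raise StructureError(
                f"PAE shape {self.pae.shape} does not match {n} residues"
            )
        if len(self.order) != n:
            raise StructureError("order length does not match residue count")
        if not np.all(np.isfinite(self.pae)) or np.any(self.pae < 0):
            raise StructureError("PAE entries must be finite and >= 0")
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise StructureError("pLDDT outside [0, 100]")


# ---------------------------------------------------------------------------
# SEQRES <-> ATOM alignment


def align_seqres_to_atom(chain: Chain) -> Dict[int, int]:
    """Map 1-based SEQRES positions to 1-based resolved-residue positions.

    Uses author numbering directly when it indexes SEQRES consistently
    (monotone, in range, letters agree); otherwise falls back to a gapped
    global alignment of the resolved sequence into SEQRES, which must place
    every resolved residue at >= 95% identity.
    """
    seqres = chain.seqres
    if not seqres:
        raise StructureError(f"chain {chain.chain_id}: empty SEQRES")
    residues = chain.residues
    resolved = "".join(r.one_letter for r in residues)

    numbering_ok = all(r.insertion_code in ("", " ") for r in residues)
    if numbering_ok:
        idx = [r.residue_index for r in residues]
        numbering_ok = (
            all(1 <= i <= len(seqres) for i in idx)
            and all(a < b for a, b in zip(idx, idx[1:]))
            and all(
                seqres[i - 1] == r.one_letter or r.one_letter == "X"
                for i, r in zip(idx, residues)
            )
        )
        if numbering_ok:
            return {r.residue_index: k + 1 for k, r in enumerate(residues)}

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    try:  # free end gaps on the SEQRES side (attribute renamed in Biopython)
        aligner.end_insertion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
    aln = aligner.align(seqres, resolved)[0]
    mapping: Dict[int, int] = {}
    matches = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            sp, rp = ts + off + 1, qs + off + 1
            mapping[sp] = rp
            if seqres[sp - 1] == resolved[rp - 1]:
                matches += 1
    if len(mapping) < len(resolved) or matches < 0.95 * len(resolved):
        raise StructureError(
            f"chain {chain.chain_id}: resolved sequence does not align into "
            f"SEQRES at >=95% identity"
        )
    return mapping


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)


def _pick_altloc(res: gemmi.Residue) -> Dict[str, gemmi.Atom]:
    """Highest occupancy wins; ties go to the lowest altloc letter ('A')."""
    best: Dict[str, gemmi.Atom] = {}
    for atom in res:
        cur = best.get(atom.name)
        if cur is None:
            best[atom.name] = atom
            continue
        if atom.occ > cur.occ or (atom.occ == cur.occ and (atom.altloc or "~") < (cur.altloc or "~")):
            best[atom.name] = atom
    return best


def read_structure(path: str | Path, dialect: str = "pdb") -> Structure:
    """Read a (multichain) protein structure from a PDB (or mmCIF) file.

    Only the first model is used; waters and other HETATM entries are
    dropped; alternate locations collapse to the highest-occupancy atom.
    When SEQRES is absent a chain's SEQRES defaults to its ATOM-derived
    sequence, making the SEQRES->ATOM map the identity.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on bad input
        raise StructureError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()

    # SEQRES per subchain, via the entity table
    seqres_by_subchain: Dict[str, str] = {}
    for ent in st.entities:
        if not ent.full_sequence:
            continue
        one = "".join(
            three_to_one(gemmi.Entity.first_mon(m)) for m in ent.full_sequence
        )
        for sub in ent.subchains:
            seqres_by_subchain[sub] = one

    model = st[0]
    chains: List[Chain] = []
    for gch in model:
        residues: List[Residue] = []
        subchain = None
        for gres in gch:
            if gres.is_water():
                continue
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = info is not None and info.is_amino_acid()
            if gres.het_flag == "H" and not is_aa:
                continue
            atoms: Dict[str, np.ndarray] = {}
            bfac: Dict[str, float] = {}
            for name, atom in _pick_altloc(gres).items():
                atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                bfac[name] = atom.b_iso
            if not atoms:
                continue
            if subchain is None:
                subchain = gres.subchain
            residues.append(
                Residue(
                    name=gres.name,
                    residue_index=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                    bfactors=bfac,
                )
            )
        if not residues:
            continue
        seqres = seqres_by_subchain.get(subchain or "", "")
        if not seqres:
            seqres = "".join(r.one_letter for r in residues)
            mapping = {k + 1: k + 1 for k in range(len(residues))}
        else:
            mapping = {}
        chains.append(
            Chain(chain_id=gch.name, seqres=seqres, residues=residues,
                  seqres_to_atom=mapping)
        )

    if not chains:
        raise StructureError(f"{path}: zero protein chains")
    resolution = float(st.resolution) if st.resolution > 0 else None
    return Structure(id=path.stem, chains=chains, resolution=resolution)


def write_structure(struct: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file with SEQRES records."""
    st = gemmi.Structure()
    st.name = struct.id
    if struct.resolution is not None:
        st.resolution = struct.resolution
    model = gemmi.Model("1")
    for chain in struct.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.residue_index, res.insertion_code or " ")
            gres.het_flag = "A"
            gres.subchain = chain.chain_id + "x"
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = res.bfactors.get(name, 0.0)
                atom.element = gemmi.Element(name[0])
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    for chain in struct.chains:
        ent = gemmi.Entity(chain.chain_id)
        ent.entity_type = gemmi.EntityType.Polymer
        ent.polymer_type = gemmi.PolymerType.PeptideL
        ent.subchains = [chain.chain_id + "x"]
        ent.full_sequence = [_THREE_FROM_ONE.get(c, "UNK") for c in chain.seqres]
        st.entities.append(ent)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Confidence JSON


def read_confidence(path: str | Path, model: Structure) -> ConfidenceData:
    """Read AlphaFold-style confidence JSON, validated against *model*.

    Accepts either the ``predicted_aligned_error`` dialect (possibly wrapped
    in a one-element list, as in the PAE files served alongside AlphaFold
    models) or a flat ``pae`` list-of-lists.  pLDDT comes from a ``plddt``
    array when present, otherwise from the model's B-factor column.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if len(data) != 1 or not isinstance(data[0], dict):
            raise StructureError(f"{path}: unsupported JSON layout")
        data = data[0]
    pae = data.get("predicted_aligned_error", data.get("pae"))
    if pae is None:
        raise StructureError(f"{path}: no PAE matrix found")
    pae = np.asarray(pae, dtype=float)
    n_model = model.n_residues
    if pae.shape != (n_model, n_model):
        raise StructureError(
            f"{path}: PAE is {pae.shape}, model has {n_model} residues"
        )
    if "plddt" in data:
        plddt = np.asarray(data["plddt"], dtype=float)
        if len(plddt) != n_model:
            raise StructureError(f"{path}: pLDDT length != model residues")
    else:
        plddt = np.array([r.plddt for c in model.chains for r in c.residues])
    ptm = data.get("ptm")
    iptm = data.get("iptm")
    return ConfidenceData(
        plddt=plddt,
        pae=pae,
        order=model.residue_order(),
        ptm=None if ptm is None else float(ptm),
        iptm=None if iptm is None else float(iptm),
    )


def write_confidence(conf: ConfidenceData, path: str | Path) -> None:
    data = {
        "predicted_aligned_error": conf.pae.tolist(),
        "plddt": conf.plddt.tolist(),
    }
    if conf.ptm is not None:
        data["ptm"] = conf.ptm
    if conf.iptm is not None:
        data["iptm"] = conf.iptm
    with open(path, "w") as fh:
        json.dump(data, fh)


# ---------------------------------------------------------------------------
# Common-residue restriction


def _align_positions(seq_a: str, seq_b: str) -> Dict[int, int]:
    """1-based position map from seq_a to seq_b via global alignment."""
    if seq_a == seq_b:
        return {i + 1: i + 1 for i in range(len(seq_a))}
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq_a, seq_b)[0]
    out: Dict[int, int] = {}
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            out[ts + off + 1] = qs + off + 1
    return out


def common_residue_restriction(
    model: Structure, native: Structure, mapping: "ChainMappingLike"
) -> Dict[str, List[Tuple[int, int]]]:
    """SEQRES positions resolved in BOTH structures, per mapped chain pair.

    Returns ``{model_chain_id: [(model_seqres_pos, native_seqres_pos), ...]}``
    in increasing model position order.  Downstream scoring must use only
    these residues, so that unresolved (often disordered) regions present in
    a full-sequence model but absent from the reference never contribute.
    """
    pairs = getattr(mapping, "pairs", mapping)
    out: Dict[str, List[Tuple[int, int]]] = {}
    for m_id, n_id in pairs.items():
        mc = model.chain(m_id)
        nc = native.chain(n_id)
        pos_map = _align_positions(mc.seqres, nc.seqres)
        common = [
            (p, pos_map[p])
            for p in mc.resolved_seqres_positions
            if p in pos_map and pos_map[p] in nc.seqres_to_atom
        ]
        if not common:
            raise StructureError(
                f"chains {m_id}->{n_id}: zero residues resolved in both structures"
            )
        out[m_id] = common
    return out


class ChainMappingLike:  # typing aid only
    pairs: Dict[str, str]
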