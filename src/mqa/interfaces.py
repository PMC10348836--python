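"""Interface definition and chain mapping for multichain complexes.

Two interface notions are used throughout:

* pairwise — the contacts between one chain pair (i, j);
* one-vs-rest — the contacts between a designated ligand chain i and the
  union of all remaining chains.

Contacts are residue pairs under one of two schemes: ``cb`` (Cβ–Cβ, Cα for
glycine; the convention behind pDockQ-style confidence scores, default
cutoff 8 Å) or ``heavy_atom`` (any heavy-atom pair; the convention behind
DockQ internals at 5 and 10 Å).  Chain correspondence between a model and a
reference is taken from MM-align output when available, or computed by
sequence assignment plus a permutation search over sequence-identical chains.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .structio import Chain, Structure, StructureError, common_residue_restriction

logger = logging.getLogger(__name__)

__all__ = [
    "ContactPair",
    "InterfaceDef",
    "ChainMapping",
    "contacts_between",
    "pairwise_interfaces",
    "one_vs_rest_interface",
    "map_chains",
    "parse_mmalign",
]


@dataclass(frozen=True)
class ContactPair:
    """A residue–residue contact across chains, in SEQRES coordinates."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    distance: float

    @property
    def key(self) -> FrozenSet[Tuple[str, int]]:
        return frozenset({(self.chain_a, self.res_a), (self.chain_b, self.res_b)})


@dataclass
class InterfaceDef:
    ligand_chain: str
    receptor_chains: Set[str]
    contacts: List[ContactPair]
    kind: str  # "pairwise" | "one_vs_rest"

    def __post_init__(self) -> None:
        if self.kind == "pairwise" and len(self.receptor_chains) != 1:
            raise ValueError("pairwise interface needs exactly one receptor chain")
        if self.ligand_chain in self.receptor_chains:
            raise ValueError("ligand chain cannot be its own receptor")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def interface_residues(self) -> Set[Tuple[str, int]]:
        """Unique residues on both sides, as (chain_id, seqres_pos)."""
        out: Set[Tuple[str, int]] = set()
        for c in self.contacts:
            out.add((c.chain_a, c.res_a))
            out.add((c.chain_b, c.res_b))
        return out


@dataclass
class ChainMapping:
    """Bijection from model chain ids to native chain ids."""

    pairs: Dict[str, str]
    source: str = "sequence"  # mmalign | sequence | permutation_search

    def __post_init__(self) -> None:
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("chain mapping is not a bijection")

    @property
    def inverse(self) -> Dict[str, str]:
        return {v: k for k, v in self.pairs.items()}

    @classmethod
    def identity(cls, chain_ids: Iterable[str]) -> "ChainMapping":
        return cls(pairs={c: c for c in chain_ids}, source="sequence")


# ---------------------------------------------------------------------------
# Contact extraction


def _residue_points(chain: Chain, scheme: str) -> Tuple[np.ndarray, np.ndarray]:
    """Coordinates and parallel array of SEQRES positions for one chain.

    Under ``cb`` each residue contributes its Cβ (Cα for glycine or when Cβ
    is missing); residues lacking both are skipped with a warning.  Under
    ``heavy_atom`` every non-hydrogen atom contributes.
    """
    coords: List[np.ndarray] = []
    labels: List[int] = []
    atom_seqres = chain.atom_to_seqres
    skipped = 0
    for k, res in enumerate(chain.residues, start=1):
        pos = atom_seqres.get(k)
        if pos is None:
            continue
        if scheme == "cb":
            xyz = res.coord("CB") if res.name != "GLY" else res.coord("CA")
            if xyz is None:
                xyz = res.coord("CA")
            if xyz is None:
                skipped += 1
                continue
            coords.append(xyz)
            labels.append(pos)
        elif scheme == "heavy_atom":
            for name, xyz in res.atoms.items():
                if name.startswith("H") or name[:1] == "D":
                    continue
                coords.append(xyz)
                labels.append(pos)
        else:
            raise ValueError(f"unknown contact scheme {scheme!r}")
    if skipped:
        logger.warning(
            "chain %s: %d residue(s) lack both CB and CA, skipped",
            chain.chain_id, skipped,
        )
    if not coords:
        raise StructureError(
            f"chain {chain.chain_id}: no usable atoms under scheme {scheme!r}"
        )
    return np.asarray(coords), np.asarray(labels)


def contacts_between(
    struct: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 8.0,
    scheme: str = "cb",
) -> List[ContactPair]:
    """Residue pairs of chains a and b within *cutoff* under *scheme*.

    Each qualifying residue pair appears once, with the minimal qualifying
    inter-atomic distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff > 0 required")
    if chain_a == chain_b:
        raise ValueError("contacts are inter-chain; got identical chains")
    ca, la = _residue_points(struct.chain(chain_a), scheme)
    cb, lb = _residue_points(struct.chain(chain_b), scheme)
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    best: Dict[Tuple[int, int], float] = {}
    for i, hits in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for j in hits:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            key = (int(la[i]), int(lb[j]))
            if d < best.get(key, np.inf):
                best[key] = d
    return [
        ContactPair(chain_a, ra, chain_b, rb, d)
        for (ra, rb), d in sorted(best.items())
    ]


def pairwise_interfaces(
    struct: Structure, cutoff: float = 8.0, scheme: str = "cb"
) -> List[InterfaceDef]:
    """One pairwise InterfaceDef per unordered chain pair with >= 1 contact."""
    if len(struct.chains) < 2:
        raise StructureError("need >= 2 chains for interfaces")
    out = []
    for a, b in itertools.combinations(struct.chain_ids, 2):
        contacts = contacts_between(struct, a, b, cutoff, scheme)
        if contacts:
            out.append(InterfaceDef(a, {b}, contacts, kind="pairwise"))
    return out


def one_vs_rest_interface(
    struct: Structure, ligand: str, cutoff: float = 8.0, scheme: str = "cb"
) -> InterfaceDef:
    """Interface of chain *ligand* against the union of all other chains."""
    others = [c for c in struct.chain_ids if c != ligand]
    if not others:
        raise StructureError("one-vs-rest needs >= 2 chains")
    struct.chain(ligand)  # raises if absent
    contacts: List[ContactPair] = []
    for other in others:
        contacts.extend(contacts_between(struct, ligand, other, cutoff, scheme))
    return InterfaceDef(ligand, set(others), contacts, kind="one_vs_rest")


# ---------------------------------------------------------------------------
# Chain mapping


def _percent_identity(seq_a: str, seq_b: str) -> float:
    if seq_a == seq_b:
        return 100.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        matches += sum(
            seq_a[ts + o] == seq_b[qs + o] for o in range(te - ts)
        )
    return 100.0 * matches / min(len(seq_a), len(seq_b))


def _pair_ca_coords(
    model: Structure, native: Structure, m_id: str, n_id: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired Cα coordinates (model, native) over SEQRES-common residues."""
    restriction = common_residue_restriction(model, native, {m_id: n_id})
    mc, nc = model.chain(m_id), native.chain(n_id)
    mov, ref = [], []
    for mp, np_ in restriction[m_id]:
        a = mc.residue_at_seqres(mp).coord("CA")
        b = nc.residue_at_seqres(np_).coord("CA")
        if a is not None and b is not None:
            mov.append(a)
            ref.append(b)
    return np.asarray(mov), np.asarray(ref)


def map_chains(
    model: Structure,
    native: Structure,
    method: str = "auto",
    min_identity: float = 30.0,
) -> ChainMapping:
    """Find the model→native chain correspondence.

    Distinct-sequence chains are matched by sequence identity alone; chains
    with identical (or ambiguously similar) sequences are resolved by
    enumerating the sequence-consistent label permutations and keeping the
    one with minimal global Cα RMSD after a single rigid superposition.
    Ties break lexicographically on the native-label tuple.
    """
    if len(model.chains) != len(native.chains):
        raise StructureError(
            f"stoichiometry mismatch: model has {len(model.chains)} chains, "
            f"native has {len(native.chains)}"
        )
    m_ids, n_ids = model.chain_ids, native.chain_ids
    ident: Dict[Tuple[str, str], float] = {}
    for m in m_ids:
        for n in n_ids:
            ident[(m, n)] = _percent_identity(
                model.chain(m).seqres, native.chain(n).seqres
            )
    best = {m: max(ident[(m, n)] for n in n_ids) for m in m_ids}
    if any(best[m] < min_identity for m in m_ids):
        bad = [m for m in m_ids if best[m] < min_identity]
        raise StructureError(
            f"no native chain matches model chain(s) {bad} at >= {min_identity}% identity"
        )
    # unambiguous assignment: only natives tying the chain's best identity
    candidates = {
        m: sorted(n for n in n_ids if ident[(m, n)] >= best[m] - 1e-9) for m in m_ids
    }

    def _consistent_perms(cand: Dict[str, List[str]]) -> List[Tuple[str, ...]]:
        return [
            perm
            for perm in itertools.permutations(n_ids)
            if all(n in cand[m] for m, n in zip(m_ids, perm))
        ]

    perms = _consistent_perms(candidates)
    if not perms:
        # best-hit graph has no perfect matching; widen to the identity floor
        candidates = {
            m: sorted(n for n in n_ids if ident[(m, n)] >= min_identity)
            for m in m_ids
        }
        perms = _consistent_perms(candidates)
    if not perms:
        raise StructureError("no sequence-consistent chain assignment exists")
    if len(perms) == 1:
        return ChainMapping(dict(zip(m_ids, perms[0])), source="sequence")

    from .dockq import superpose  # local import to avoid a cycle

    coords: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for m in m_ids:
        for n in set(n for p in perms for n in [dict(zip(m_ids, p))[m]]):
            coords[(m, n)] = _pair_ca_coords(model, native, m, n)
    scored = []
    for perm in perms:
        mov = np.concatenate([coords[(m, n)][0] for m, n in zip(m_ids, perm)])
        ref = np.concatenate([coords[(m, n)][1] for m, n in zip(m_ids, perm)])
        if len(mov) < 3:
            rmsd = float("inf")
        else:
            _, _, rmsd = superpose(ref, mov)
        scored.append((rmsd, perm))
    scored.sort(key=lambda t: (t[0], t[1]))
    return ChainMapping(dict(zip(m_ids, scored[0][1])), source="permutation_search")


# ---------------------------------------------------------------------------
# MM-align output parsing

_TM_RE = re.compile(
    r"TM-score\s*=\s*([0-9.]+)\s*\(.*normalized by length of Structure_(\d)", re.I
)
_NAME_RE = re.compile(r"Name of Structure_(\d):\s*(\S+)")


def parse_mmalign(text: str) -> Tuple[float, ChainMapping]:
    """Parse MM-align stdout into (MM-score, chain mapping).

    The returned score is the TM-score normalized by the reference
    (Structure_2) length.  The chain correspondence pairs, in order, the
    chain lists appended after colons in the two structure names
    (``model.pdb:A:B`` vs ``native.pdb:A:B``).
    """
    scores: Dict[str, float] = {}
    for m in _TM_RE.finditer(text):
        scores[m.group(2)] = float(m.group(1))
    if not scores:
        raise ValueError("no TM-score lines found in MM-align output")
    score = scores.get("2", next(iter(scores.values())))

    names: Dict[str, str] = {m.group(1): m.group(2) for m in _NAME_RE.finditer(text)}
    mapping: Optional[ChainMapping] = None
    if "1" in names and "2" in names:
        chains1 = names["1"].split(":")[1:]
        chains2 = names["2"].split(":")[1:]
        if chains1 and len(chains1) == len(chains2):
            mapping = ChainMapping(dict(zip(chains1, chains2)), source="mmalign")
    if mapping is None:
        raise ValueError("cannot infer chain correspondence from MM-align output")
    return score, mapping
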