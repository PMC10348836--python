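"""Seeded generators for toy complexes, perturbed models and confidence data.

The generator builds idealized poly-helical chains (Cα plus an explicit Cβ
per residue) arranged on a ring or a line so that adjacent chains form
genuine interfaces under both contact schemes.  "Models" are produced by
rigid-body perturbation of individual chains, so the per-chain docking
truth is known by construction:

* small or zero perturbation  -> chain correctly placed;
* large translation           -> chain undocked (interface lost);
* in-place flip               -> chain *mis*-docked: it still packs against
  its neighbours with a large interface, but the native contact pattern is
  destroyed.  This is the "large, confident but wrong interface" regime in
  which size-and-pLDDT confidence scores overrate a model and only the
  predicted aligned error reveals the problem.

Synthetic confidence follows the same truth: pLDDT is high everywhere
(interface quality estimators are routinely confident even on wrong docks),
while PAE is drawn around a low mean for correctly placed chain pairs and a
high mean for misdocked ones, truncated to AlphaFold's [0, 31.75] Å range.

Everything is deterministic given ``GeneratorSpec.seed``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .structio import Chain, ConfidenceData, Residue, Structure, three_to_one
from .confidence import SigmoidCoeffs, sigmoid

__all__ = [
    "Perturbation",
    "GeneratorSpec",
    "make_complex",
    "perturb_model",
    "misdocked_chains",
    "synth_confidence",
    "apply_plddt",
    "sample_sigmoid",
    "generate_case",
    "PAE_CEILING",
]

PAE_CEILING = 31.75

# helix geometry (idealized alpha helix)
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_CB_OFFSET = 1.5
_CHAIN_SPACING = 10.0

_AA20_NO_GLY = "ACDEFHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "H": "HIS",
    "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN", "P": "PRO",
    "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL", "W": "TRP",
    "Y": "TYR", "G": "GLY",
}


@dataclass(frozen=True)
class Perturbation:
    """Rigid-body perturbation of one chain.

    ``flip`` replaces the random rotation with a deterministic 180° turn
    about the radial axis through the chain centroid plus a small approach
    toward the complex centre: the chain stays in place (large interface)
    but every native contact is destroyed.
    """

    rotation_deg: float = 0.0
    translation: float = 0.0
    flip: bool = False

    @property
    def is_misdocking(self) -> bool:
        return self.flip or self.translation >= 10.0 or self.rotation_deg >= 90.0


@dataclass
class GeneratorSpec:
    n_chains: int = 3
    chain_lengths: Optional[List[int]] = None  # default: 30 residues each
    arrangement: str = "ring"  # ring | line
    perturbations: Optional[List[Perturbation]] = None
    homomer: bool = False
    plddt_noise_sd: float = 2.0
    pae_noise_sd: float = 1.0
    pae_right_mean: float = 2.0
    pae_wrong_mean: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_chains <= 6:
            raise ValueError("n_chains must be in 2..6")
        if self.chain_lengths is None:
            self.chain_lengths = [30] * self.n_chains
        if len(self.chain_lengths) != self.n_chains:
            raise ValueError("chain_lengths must match n_chains")
        if any(l < 5 for l in self.chain_lengths):
            raise ValueError("chain lengths must be >= 5")
        if self.arrangement not in ("ring", "line"):
            raise ValueError("arrangement must be 'ring' or 'line'")
        if min(self.plddt_noise_sd, self.pae_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.pae_wrong_mean <= self.pae_right_mean:
            raise ValueError("pae_wrong_mean must exceed pae_right_mean")
        if self.perturbations is not None and len(self.perturbations) != self.n_chains:
            raise ValueError("need one Perturbation per chain")


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream])


def _helix_chain(
    chain_id: str, sequence: str, spec: GeneratorSpec, k: int
) -> Chain:
    """Idealized helical chain placed as the k-th subunit.

    Ring complexes are C_n symmetric: chain k is chain 0 rotated by
    2*pi*k/n about the ring axis, so a homomeric ring has identical
    interfaces.  Line complexes are translated copies.
    """
    if spec.arrangement == "line":
        origin = np.array([k * _CHAIN_SPACING, 0.0, 0.0])
        ring_rot = np.eye(3)
    else:
        radius = _CHAIN_SPACING / (2.0 * math.sin(math.pi / spec.n_chains))
        origin = np.array([radius, 0.0, 0.0])
        phi = 2.0 * math.pi * k / spec.n_chains
        c, s = math.cos(phi), math.sin(phi)
        ring_rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    residues = []
    for i, letter in enumerate(sequence):
        theta = _HELIX_TWIST * i
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = origin + _HELIX_RADIUS * radial + np.array([0.0, 0.0, _HELIX_RISE * i])
        cb = ca + _CB_OFFSET * radial
        residues.append(
            Residue(
                name=_ONE_TO_THREE[letter],
                residue_index=i + 1,
                atoms={"CA": ring_rot @ ca, "CB": ring_rot @ cb},
                bfactors={"CA": 0.0, "CB": 0.0},
            )
        )
    return Chain(chain_id=chain_id, seqres=sequence, residues=residues)


def make_complex(spec: GeneratorSpec) -> Structure:
    """Build the deterministic 'native' complex described by *spec*."""
    rng = _rng(spec, 1)
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    if spec.homomer:
        length = spec.chain_lengths[0]
        if any(l != length for l in spec.chain_lengths):
            raise ValueError("homomer requires equal chain lengths")
        seq = "".join(rng.choice(list(_AA20_NO_GLY), size=length))
        sequences = [seq] * spec.n_chains
    else:
        sequences = [
            "".join(rng.choice(list(_AA20_NO_GLY), size=l))
            for l in spec.chain_lengths
        ]
    chains = [
        _helix_chain(cid, seq, spec, k)
        for k, (cid, seq) in enumerate(zip(chain_ids, sequences))
    ]
    return Structure(id=f"synth{spec.seed}", chains=chains)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def _transform_chain(chain: Chain, R: Optional[np.ndarray], t: np.ndarray) -> Chain:
    """Rigidly move a chain about its Cα centroid; R=None copies exactly."""
    center = np.mean(
        [r.atoms["CA"] for r in chain.residues], axis=0
    )
    new_residues = []
    for res in chain.residues:
        if R is None:
            atoms = {name: xyz.copy() + t for name, xyz in res.atoms.items()}
        else:
            atoms = {
                name: (R @ (xyz - center)) + center + t
                for name, xyz in res.atoms.items()
            }
        new_residues.append(
            Residue(
                name=res.name,
                residue_index=res.residue_index,
                insertion_code=res.insertion_code,
                atoms=atoms,
                bfactors=dict(res.bfactors),
            )
        )
    return Chain(
        chain_id=chain.chain_id,
        seqres=chain.seqres,
        residues=new_residues,
        seqres_to_atom=dict(chain.seqres_to_atom),
    )


def perturb_model(native: Structure, spec: GeneratorSpec) -> Structure:
    """Apply the per-chain rigid perturbations of *spec* to *native*."""
    perts = spec.perturbations or [Perturbation()] * spec.n_chains
    rng = _rng(spec, 2)
    complex_center = np.mean(
        [r.atoms["CA"] for c in native.chains for r in c.residues], axis=0
    )
    chains = []
    for chain, pert in zip(native.chains, perts):
        # draw per-chain randomness unconditionally to keep streams aligned
        axis = rng.standard_normal(3)
        direction = rng.standard_normal(3)
        if pert.flip:
            centroid = np.mean([r.atoms["CA"] for r in chain.residues], axis=0)
            radial = centroid - complex_center
            radial[2] = 0.0
            if np.linalg.norm(radial) < 1e-9:
                radial = np.array([1.0, 0.0, 0.0])
            R = _rotation_matrix(radial, math.pi)
            approach = -radial / np.linalg.norm(radial) * 1.5
            chains.append(_transform_chain(chain, R, approach))
            continue
        if pert.rotation_deg == 0.0 and pert.translation == 0.0:
            # exact copy: identity transforms must be bit-identical
            chains.append(_transform_chain(chain, None, np.zeros(3)))
            continue
        R = np.eye(3)
        if pert.rotation_deg:
            R = _rotation_matrix(axis, math.radians(pert.rotation_deg))
        t = np.zeros(3)
        if pert.translation:
            t = direction / np.linalg.norm(direction) * pert.translation
        chains.append(_transform_chain(chain, R, t))
    return Structure(id=native.id + "_model", chains=chains)


def misdocked_chains(spec: GeneratorSpec) -> Set[str]:
    """Chain ids whose perturbation is large enough to count as misdocked."""
    perts = spec.perturbations or [Perturbation()] * spec.n_chains
    return {
        chr(ord("A") + k) for k, p in enumerate(perts) if p.is_misdocking
    }


def synth_confidence(
    native: Structure, model: Structure, spec: GeneratorSpec
) -> ConfidenceData:
    """Quality-consistent synthetic pLDDT/PAE for *model*.

    pLDDT is high (90 minus half-normal noise) for every residue.  PAE for
    residue pairs within a chain or across correctly docked chain pairs is
    drawn around ``pae_right_mean``; pairs involving a misdocked chain are
    drawn around ``pae_wrong_mean``; everything truncated to [0, 31.75] Å.
    """
    rng = _rng(spec, 3)
    n = model.n_residues
    plddt = np.clip(90.0 - np.abs(rng.normal(0.0, spec.plddt_noise_sd, n)), 0, 100)

    wrong = misdocked_chains(spec)
    chain_of = np.array([cid for cid, _ in model.residue_order()])
    base = rng.normal(spec.pae_right_mean, spec.pae_noise_sd, (n, n))
    wrong_draw = rng.normal(spec.pae_wrong_mean, spec.pae_noise_sd, (n, n))
    cross = chain_of[:, None] != chain_of[None, :]
    involves_wrong = np.isin(chain_of, list(wrong)) if wrong else np.zeros(n, bool)
    bad_pair = cross & (involves_wrong[:, None] | involves_wrong[None, :])
    pae = np.where(bad_pair, wrong_draw, base)
    np.fill_diagonal(pae, 0.0)
    pae = np.clip(pae, 0.0, PAE_CEILING)
    return ConfidenceData(plddt=plddt, pae=pae, order=model.residue_order())


def apply_plddt(struct: Structure, plddt: np.ndarray) -> None:
    """Write a per-residue pLDDT vector into the B-factor column in place."""
    vals = np.asarray(plddt, dtype=float)
    if len(vals) != struct.n_residues:
        raise ValueError("pLDDT length does not match structure")
    i = 0
    for chain in struct.chains:
        for res in chain.residues:
            for name in res.atoms:
                res.bfactors[name] = float(vals[i])
            i += 1


def sample_sigmoid(
    coeffs: SigmoidCoeffs,
    n: int,
    noise_sd: float = 0.0,
    x_range: Tuple[float, float] = (0.0, 130.0),
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) calibration data from a known sigmoid, y clamped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(x_range[0], x_range[1], n)
    ys = np.array([sigmoid(x, coeffs) for x in xs])
    if noise_sd > 0:
        ys = ys + rng.normal(0.0, noise_sd, n)
    return xs, np.clip(ys, 0.0, 1.0)


def generate_case(
    seed: int,
    n_chains: int = 3,
    misdock: Sequence[int] = (),
    undock: Sequence[int] = (),
    arrangement: str = "ring",
    homomer: bool = False,
    chain_lengths: Optional[List[int]] = None,
    **confidence_kwargs,
) -> Tuple[Structure, Structure, ConfidenceData, Set[str]]:
    """Convenience bundle: native, model, confidence and misdocked labels.

    ``misdock`` lists chain indices flipped in place (wrong but contactful);
    ``undock`` lists chain indices translated 50 Å away (interface lost).
    """
    perts = []
    for k in range(n_chains):
        if k in misdock:
            perts.append(Perturbation(flip=True))
        elif k in undock:
            perts.append(Perturbation(translation=50.0))
        else:
            perts.append(Perturbation())
    spec = GeneratorSpec(
        n_chains=n_chains,
        chain_lengths=chain_lengths,
        arrangement=arrangement,
        perturbations=perts,
        homomer=homomer,
        seed=seed,
        **confidence_kwargs,
    )
    native = make_complex(spec)
    model = perturb_model(native, spec)
    conf = synth_confidence(native, model, spec)
    apply_plddt(model, conf.plddt)
    return native, model, conf, misdocked_chains(spec)
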