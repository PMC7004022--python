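"""Trained per-atom model sets and the geometry -> global-moments pipeline.

A complete monomer force-field model comprises 3 atomic-energy models and
3 x 9 multipole-component models (O, H1, H2; ranks 0-2 in the local frame),
all trained on the same configurations.  ``KrigingStack`` bundles models that
share one training-feature matrix so that a single kernel evaluation serves
every property -- the hot path during dynamics.

``molecule_global_moments`` runs the full prediction pipeline for a batch of
molecules: internal features -> local-frame moments -> rotation into the
global frame via each atom's axis system.  Its Jacobian with respect to the
nine molecular coordinates (the polarization response used in the forces)
combines analytic kernel derivatives and the analytic B-matrix with
complex-step differentiation of the frame rotation, which is exact to
machine precision.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np

from .geometry import feature_jacobian, features_from_positions, frame_rotations
from .kriging import KrigingResults, PSOSettings, train
from .multipoles import COMPONENT_NAMES, rotate_moment_array

__all__ = [
    "KrigingStack",
    "WaterModelSet",
    "molecule_global_moments",
    "molecule_moment_jacobians",
]

_CS_STEP = 1e-30  # complex-step size; derivative error is O(step^2) ~ exact
_ATOM_NAMES = ("O", "H1", "H2")


class KrigingStack:
    """Vectorised evaluation of kriging models sharing training features."""

    def __init__(self, results: Sequence[KrigingResults]):
        if len(results) == 0:
            raise ValueError("empty model stack")
        F0 = results[0].training_features
        for r in results:
            if r.training_features.shape != F0.shape or not np.allclose(
                r.training_features, F0
            ):
                raise ValueError("stacked models must share training features")
        self.results = list(results)
        self.features = F0  # (N, 3)
        self.mu = np.array([r.mu for r in results])
        self.weights = np.array([r.weights for r in results])  # (K, N)
        self.theta = np.array([r.theta for r in results])      # (K, 3)
        self.all_p2 = all(np.all(r.p == 2.0) for r in results)
        if not self.all_p2:
            raise ValueError("stacked evaluation requires p = 2 models")

    def __len__(self) -> int:
        return len(self.results)

    def _kernels(self, feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        diff = feats[:, None, :] - self.features[None, :, :]     # (M, N, 3)
        expo = np.einsum("kh,mnh->kmn", self.theta, diff**2)
        return np.exp(-expo), diff                               # (K, M, N)

    def predict(self, feats: np.ndarray) -> np.ndarray:
        """(M, 3) features -> (M, K) predictions."""
        K, _ = self._kernels(np.atleast_2d(feats))
        return self.mu[None, :] + np.einsum("kmn,kn->mk", K, self.weights)

    def predict_with_gradients(self, feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(M, 3) -> predictions (M, K) and feature gradients (M, K, 3)."""
        feats = np.atleast_2d(feats)
        K, diff = self._kernels(feats)
        pred = self.mu[None, :] + np.einsum("kmn,kn->mk", K, self.weights)
        grad = np.einsum(
            "kmn,kn,mnh,kh->mkh", K, self.weights, diff, -2.0 * self.theta
        )
        return pred, grad


def molecule_global_moments(
    positions: np.ndarray, moment_stack: KrigingStack
) -> tuple[np.ndarray, np.ndarray]:
    """Predict global-frame moments for a batch of molecules.

    positions: (M, 3, 3).  Returns (global moments (M, 3, 9), local moments
    (M, 3, 9)).  The stack must hold the 27 moment models in atom-major
    component order.
    """
    pos = np.asarray(positions, dtype=float)
    feats = features_from_positions(pos)                        # (M, 3)
    q_loc = moment_stack.predict(feats).reshape(-1, 3, 9)       # (M, 3, 9)
    rots = frame_rotations(pos)                                 # (M, 3, 3, 3)
    q_glob = rotate_moment_array(q_loc, rots)
    return q_glob, q_loc


def molecule_moment_jacobians(
    positions: np.ndarray,
    moment_stack: KrigingStack | None,
    q_loc: np.ndarray,
) -> np.ndarray:
    """d(global moments)/d(molecular coordinates), shape (M, 3, 9, 9).

    The last axis is the molecule's nine Cartesian coordinates (atom-major).
    Two contributions: (a) the frame rotation changes with geometry (applied
    to the current local moments; computed by complex step through the frame
    builder, exact to machine precision); (b) the local moments themselves
    change with the internal coordinates (analytic kernel gradients chained
    with the B-matrix, then rotated).  Pass ``moment_stack=None`` for
    geometry-frozen local moments (rigid-molecule dynamics): only (a) remains.
    """
    pos = np.asarray(positions, dtype=float)
    m = pos.shape[0]
    q_loc = np.asarray(q_loc)

    # (a) complex-step the frame rotation, batched over the 9 coordinates
    eye = np.eye(9).reshape(9, 3, 3)
    pos_c = pos[:, None] + 1j * _CS_STEP * eye[None, :]          # (M, 9, 3, 3)
    rots_c = frame_rotations(pos_c)                              # (M, 9, 3, 3, 3)
    q_g = rotate_moment_array(q_loc[:, None, :, :], rots_c)      # (M, 9, 3, 9)
    jac = np.transpose(q_g.imag / _CS_STEP, (0, 2, 3, 1))        # (M, 3, 9, 9)

    if moment_stack is not None:
        feats = features_from_positions(pos)
        _, dq_df = moment_stack.predict_with_gradients(feats)    # (M, 27, 3)
        dq_df = dq_df.reshape(m, 3, 9, 3)
        B = np.stack([feature_jacobian(p).reshape(3, 9) for p in pos])  # (M, 3, 9)
        dq_loc = np.einsum("makh,mhx->maxk", dq_df, B)           # (M, 3, 9x, 9k)
        rots = frame_rotations(pos)                              # (M, 3, 3, 3)
        dq_glob = rotate_moment_array(dq_loc, rots[:, :, None])  # rotate per coord
        jac = jac + np.transpose(dq_glob, (0, 1, 3, 2))
    return jac


@dataclasses.dataclass
class WaterModelSet:
    """The trained monomer model family: 3 energy + 27 moment models."""

    energy: list            # 3 x KrigingResults (O, H1, H2)
    moments: list           # 3 x 9 KrigingResults, or [] if not trained
    provenance: dict = dataclasses.field(default_factory=dict)

    def energy_stack(self) -> KrigingStack:
        return KrigingStack(self.energy)

    def moment_stack(self) -> KrigingStack:
        if not self.moments:
            raise ValueError("model set was trained without multipole models")
        return KrigingStack([m for atom in self.moments for m in atom])

    @classmethod
    def train(
        cls,
        labelled_train: Sequence,
        optimize_p: bool = False,
        pso: PSOSettings | None = None,
        moment_pso: PSOSettings | None = None,
        rng_seed: int = 0,
        include_moments: bool = True,
        provenance: dict | None = None,
    ) -> "WaterModelSet":
        """Train all per-atom models on one training split.

        ``moment_pso`` allows a lighter swarm for the 27 moment models (their
        targets are low-amplitude and near-linear in the features); defaults
        to the energy settings.
        """
        energy = [
            train(labelled_train, "energy", a, optimize_p=optimize_p, pso=pso,
                  rng_seed=rng_seed + a)
            for a in range(3)
        ]
        moments: list = []
        if include_moments:
            mpso = moment_pso or pso
            for a in range(3):
                moments.append(
                    [
                        train(labelled_train, "moment", a, c, optimize_p=optimize_p,
                              pso=mpso, rng_seed=rng_seed + 100 + 9 * a + c)
                        for c in range(9)
                    ]
                )
        return cls(energy, moments, provenance or {})

    # -- directory serialization ------------------------------------------
    def save(self, directory: str | pathlib.Path) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        files = {}
        for a, res in enumerate(self.energy):
            name = f"energy_{_ATOM_NAMES[a]}.json"
            res.save(d / name)
            files[f"energy:{a}"] = name
        for a, atom_models in enumerate(self.moments):
            for c, res in enumerate(atom_models):
                name = f"moment_{_ATOM_NAMES[a]}_{COMPONENT_NAMES[c]}.json"
                res.save(d / name)
                files[f"moment:{a}:{c}"] = name
        manifest = {
            "format_version": 1,
            "files": files,
            "provenance": self.provenance,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | pathlib.Path) -> "WaterModelSet":
        d = pathlib.Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest.get("format_version") != 1:
            raise ValueError("unsupported model-set format version")
        files = manifest["files"]
        energy = [KrigingResults.load(d / files[f"energy:{a}"]) for a in range(3)]
        moments = []
        if "moment:0:0" in files:
            moments = [
                [KrigingResults.load(d / files[f"moment:{a}:{c}"]) for c in range(9)]
                for a in range(3)
            ]
        return cls(energy, moments, manifest.get("provenance", {}))
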