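"""XYZ geometry and trajectory I/O (via MDAnalysis).

Configurations and trajectories are exchanged as plain multi-frame XYZ
(element symbol + three coordinates in angstrom per line).  Water molecules
are identified by ordering: consecutive (O, H, H) triples.
"""

from __future__ import annotations

import pathlib
import warnings
from typing import Sequence

import numpy as np

from .geometry import WaterConfiguration

__all__ = [
    "write_frames",
    "read_frames",
    "write_configurations",
    "read_configurations",
    "write_labelled_csv",
    "read_labelled_csv",
]


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def write_frames(
    path: str | pathlib.Path,
    frames: np.ndarray,
    symbols: Sequence[str],
    precision: int = 8,
) -> None:
    """Write (F, n_atoms, 3) positions as multi-frame XYZ."""
    mda = _mda()
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    if len(symbols) != n_atoms:
        raise ValueError("symbol count does not match atom count")
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", list(symbols))
    u.add_TopologyAttr("elements", list(symbols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, precision=precision) as w:
            for frame in frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_frames(path: str | pathlib.Path) -> tuple[np.ndarray, list[str]]:
    """Read multi-frame XYZ; returns ((F, n_atoms, 3) positions, symbols)."""
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        symbols = [str(n) for n in u.atoms.names]
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return frames, symbols


def write_configurations(
    path: str | pathlib.Path, configs: Sequence[WaterConfiguration]
) -> None:
    """Write monomer configurations as one XYZ frame each."""
    frames = np.array([c.positions for c in configs])
    write_frames(path, frames, ["O", "H", "H"])


def read_configurations(path: str | pathlib.Path) -> list[WaterConfiguration]:
    """Read one monomer per XYZ frame (atom order O, H, H)."""
    frames, symbols = read_frames(path)
    if [s[0].upper() for s in symbols] != ["O", "H", "H"]:
        raise ValueError(f"expected an (O, H, H) monomer per frame, got {symbols}")
    return [WaterConfiguration(f, i) for i, f in enumerate(frames)]


# -- labelled-ensemble table ----------------------------------------------
# One row per configuration: positions (9), features (3), atomic energies
# (3, kJ/mol), local-frame moments (3 x 9, e A^l) and L(Omega) (3, Ha).

_ATOMS = ("O", "H1", "H2")


def _labelled_columns() -> list[str]:
    from .multipoles import COMPONENT_NAMES

    cols = [f"pos_{a}_{c}" for a in _ATOMS for c in "xyz"]
    cols += ["r1", "r2", "theta"]
    cols += [f"energy_{a}" for a in _ATOMS]
    cols += [f"moment_{a}_{m}" for a in _ATOMS for m in COMPONENT_NAMES]
    cols += [f"lomega_{a}" for a in _ATOMS]
    return cols


def write_labelled_csv(path: str | pathlib.Path, labelled: Sequence) -> None:
    """Write a labelled ensemble as a columnar CSV (documented schema)."""
    import pandas as pd

    from .geometry import features_from_positions

    rows = []
    for lc in labelled:
        row = list(lc.config.positions.ravel())
        row += list(features_from_positions(lc.config.positions))
        row += list(lc.atomic_energies)
        for m in lc.atomic_moments:
            row += list(m.components)
        row += list(lc.integration_errors)
        rows.append(row)
    pd.DataFrame(rows, columns=_labelled_columns()).to_csv(path, index=False)


def read_labelled_csv(path: str | pathlib.Path) -> list:
    """Read a labelled ensemble written by :func:`write_labelled_csv`."""
    import pandas as pd

    from .multipoles import MultipoleSet
    from .surrogate import LabelledConfiguration

    df = pd.read_csv(path)
    missing = set(_labelled_columns()) - set(df.columns)
    if missing:
        raise ValueError(f"labelled ensemble file missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        pos = row.iloc[0:9].to_numpy(dtype=float).reshape(3, 3)
        energies = row[[f"energy_{a}" for a in _ATOMS]].to_numpy(dtype=float)
        moments = []
        for a in _ATOMS:
            comp = row.filter(like=f"moment_{a}_").to_numpy(dtype=float)
            moments.append(MultipoleSet(comp, frame="local"))
        lomega = row[[f"lomega_{a}" for a in _ATOMS]].to_numpy(dtype=float)
        out.append(
            LabelledConfiguration(WaterConfiguration(pos, int(i)), energies, moments, lomega)
        )
    return out
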