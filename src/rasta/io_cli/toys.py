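"""Deterministic synthetic bead molecules for tests and demos.

These stand in for PDB inputs so nothing needs downloading.  All kinds are
connected under the default neighbor radius of the prior; the
``random-cluster`` kind is chirally asymmetric (almost surely), which the
enantiomer-alignment tests rely on.
"""

from __future__ import annotations

import numpy as np

from rasta.bead_model import BeadModel, default_width_for_fwhm

__all__ = ["make_toy_molecule", "TOY_KINDS"]

TOY_KINDS = ("chain", "ring", "random-cluster", "two-bead")


def make_toy_molecule(
    kind: str,
    m: int,
    spacing: float = 1.5,
    seed: int = 0,
    height: float = 7.0,
    width: float | None = None,
) -> BeadModel:
    """Build a toy molecule of `m` beads.

    * ``chain``: collinear beads along x at `spacing` Å intervals;
    * ``ring``: regular m-gon in the xy plane with nearest-neighbor
      distance `spacing`;
    * ``random-cluster``: sequential random growth, each new bead placed
      `spacing` Å from a random existing bead, rejecting overlaps closer
      than ``0.8 * spacing``; centered; chirally asymmetric;
    * ``two-bead``: two beads `spacing` Å apart along x (m must be 2).

    Deterministic given `seed`.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if width is None:
        width = default_width_for_fwhm(2.0)
    rng = np.random.default_rng(seed)
    if kind == "chain":
        pos = np.zeros((m, 3))
        pos[:, 0] = spacing * np.arange(m)
    elif kind == "ring":
        if m < 3:
            raise ValueError("ring needs m >= 3")
        # circumradius so adjacent vertices are `spacing` apart
        radius = spacing / (2.0 * np.sin(np.pi / m))
        ang = 2.0 * np.pi * np.arange(m) / m
        pos = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(m)])
    elif kind == "random-cluster":
        pos_list = [np.zeros(3)]
        while len(pos_list) < m:
            anchor = pos_list[rng.integers(len(pos_list))]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            candidate = anchor + spacing * direction
            dists = np.linalg.norm(np.array(pos_list) - candidate, axis=1)
            if np.min(dists) >= 0.8 * spacing:
                pos_list.append(candidate)
        pos = np.array(pos_list)
    elif kind == "two-bead":
        if m != 2:
            raise ValueError("two-bead requires m == 2")
        pos = np.array([[0.0, 0.0, 0.0], [spacing, 0.0, 0.0]])
    else:
        raise ValueError(f"unknown kind {kind!r}; choose from {TOY_KINDS}")
    pos = pos - pos.mean(axis=0)
    return BeadModel(positions=pos, height=height, width=width)
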