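"""Low-level 3-D geometry: dihedral angles and internal-coordinate atom placement.

All angles at this layer are in degrees unless a function name says otherwise;
positions are Cartesian, in Angstrom.  Every routine accepts batched inputs
(leading axes broadcast) so that packers can rebuild many conformations at once.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "bond_angle", "place_atom", "wrap_degrees", "wrap_radians"]


def wrap_degrees(a):
    """Wrap angle(s) to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w


def wrap_radians(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    return -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)


def dihedral(p0, p1, p2, p3):
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the atan2 formulation, which is numerically stable near 0 and 180.
    Inputs may carry leading batch axes; the last axis must be 3.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    n1 = np.cross(b0, b1u)
    n2 = np.cross(b1u, b2)
    m1 = np.cross(n1, b1u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(-y, x))
    return wrap_degrees(ang)


def bond_angle(p0, p1, p2):
    """Angle p0-p1-p2 in degrees, in [0, 180]."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    v1 = p0 - p1
    v2 = p2 - p1
    v1 = v1 / np.linalg.norm(v1, axis=-1, keepdims=True)
    v2 = v2 / np.linalg.norm(v2, axis=-1, keepdims=True)
    c = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def place_atom(a, b, c, bond_length, angle_deg, dihedral_deg):
    """Place atom D from internal coordinates relative to the chain a-b-c.

    D is positioned so that |c-D| = ``bond_length``, the angle b-c-D equals
    ``angle_deg`` and the signed dihedral a-b-c-D equals ``dihedral_deg``
    (natural extension reference frame).  Batched over leading axes of the
    position arguments and/or the dihedral argument.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(np.asarray(angle_deg, dtype=float))
    chi = np.radians(np.asarray(dihedral_deg, dtype=float))
    r = np.asarray(bond_length, dtype=float)

    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -r * np.cos(theta) * np.ones_like(chi),
            r * np.sin(theta) * np.cos(chi),
            r * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return (
        c
        + d_local[..., 0:1] * bc
        + d_local[..., 1:2] * m
        + d_local[..., 2:3] * n
    )
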