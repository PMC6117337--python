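"""MRG double-cable myelinated axon: geometry construction.

The fiber is the McIntyre–Richardson–Grill (MRG) mammalian motor axon:
21 nodes of Ranvier separated by 20 internodal regions, each internode
being the sequence MYSA–FLUT–6×STIN–FLUT–MYSA (myelin attachment,
paranode main segment, and six internodal segments).  All geometric and
passive-electrical parameters are interpolated from the published table
for nine discrete fiber diameters between 5.7 and 16 µm; intermediate
diameters are not supported.

Compartment coordinates are expressed as signed longitudinal offsets from
the center (11th) node, so a fiber is placed in the tissue simply by
adding the center-node position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FiberGeometry",
    "build_axon",
    "place_axon",
    "supported_diameters",
    "internodal_length",
    "NODE", "MYSA", "FLUT", "STIN",
]

# compartment type codes
NODE, MYSA, FLUT, STIN = 0, 1, 2, 3

N_NODES = 21
N_INTERNODES = 20
STIN_PER_INTERNODE = 6

# ---------------------------------------------------------------------------
# Diameter-dependent morphology table (fiberD in µm):
#   axonD   — internodal axon diameter (STIN, FLUT)
#   nodeD   — node / MYSA diameter
#   deltax  — node-to-node separation (internodal length L)
#   flutL   — FLUT (paranode2) length
#   nl      — number of myelin lamellae
# Node length is 1 µm and MYSA length 3 µm for every diameter.
_TABLE = {
    5.7:  dict(axonD=3.4,  nodeD=1.9, deltax=500.0,  flutL=35.0, nl=80),
    7.3:  dict(axonD=4.6,  nodeD=2.4, deltax=750.0,  flutL=38.0, nl=100),
    8.7:  dict(axonD=5.8,  nodeD=2.8, deltax=1000.0, flutL=40.0, nl=110),
    10.0: dict(axonD=6.9,  nodeD=3.3, deltax=1150.0, flutL=46.0, nl=120),
    11.5: dict(axonD=8.1,  nodeD=3.7, deltax=1250.0, flutL=50.0, nl=130),
    12.8: dict(axonD=9.2,  nodeD=4.2, deltax=1350.0, flutL=54.0, nl=135),
    14.0: dict(axonD=10.4, nodeD=4.7, deltax=1400.0, flutL=56.0, nl=140),
    15.0: dict(axonD=11.5, nodeD=5.0, deltax=1450.0, flutL=58.0, nl=145),
    16.0: dict(axonD=12.7, nodeD=5.5, deltax=1500.0, flutL=60.0, nl=150),
}

NODE_LENGTH = 1.0     # µm
MYSA_LENGTH = 3.0     # µm

# periaxonal space widths, µm
SPACE_NODE_MYSA = 0.002
SPACE_FLUT_STIN = 0.004


def supported_diameters() -> tuple[float, ...]:
    return tuple(sorted(_TABLE))


def internodal_length(fiber_diameter: float) -> float:
    """Node-to-node separation L (µm) for a supported diameter."""
    return build_axon(fiber_diameter).internodal_length


@dataclass(frozen=True)
class FiberGeometry:
    """Compartmentalized MRG fiber of a given diameter.

    Arrays are ordered proximal→distal along z.  ``z_offsets`` are
    compartment centers (µm) relative to the center node; ``node_indices``
    locates the 21 nodes within the compartment arrays.
    """

    fiber_diameter: float       # outer (myelin) diameter, µm
    axon_diameter: float        # internodal axolemma diameter, µm
    node_diameter: float        # node & MYSA diameter, µm
    internodal_length: float    # L, node-to-node, µm
    flut_length: float          # µm
    stin_length: float          # one of six segments, µm
    n_lamellae: int
    comp_types: np.ndarray      # (n_comp,) int codes NODE/MYSA/FLUT/STIN
    lengths: np.ndarray         # (n_comp,) µm
    diameters: np.ndarray       # (n_comp,) axolemma diameter, µm
    z_offsets: np.ndarray       # (n_comp,) center offset from center node, µm
    node_indices: np.ndarray    # (21,) indices into comp arrays

    @property
    def n_compartments(self) -> int:
        return self.comp_types.size


def build_axon(fiber_diameter: float) -> FiberGeometry:
    """Construct the 21-node / 20-internode MRG geometry for ``fiber_diameter``.

    Raises ``ValueError`` for diameters absent from the MRG table.
    """
    d = float(fiber_diameter)
    if d not in _TABLE:
        raise ValueError(
            f"unsupported fiber diameter {d} µm; supported: {supported_diameters()}"
        )
    row = _TABLE[d]
    L = row["deltax"]
    stin_len = (L - NODE_LENGTH - 2 * MYSA_LENGTH - 2 * row["flutL"]) / STIN_PER_INTERNODE

    types: list[int] = []
    lengths: list[float] = []
    diams: list[float] = []

    internode_seq = (
        [(MYSA, MYSA_LENGTH, row["nodeD"])]
        + [(FLUT, row["flutL"], row["axonD"])]
        + [(STIN, stin_len, row["axonD"])] * STIN_PER_INTERNODE
        + [(FLUT, row["flutL"], row["axonD"])]
        + [(MYSA, MYSA_LENGTH, row["nodeD"])]
    )
    for i in range(N_NODES):
        types.append(NODE)
        lengths.append(NODE_LENGTH)
        diams.append(row["nodeD"])
        if i < N_INTERNODES:
            for t, ln, dd in internode_seq:
                types.append(t)
                lengths.append(ln)
                diams.append(dd)

    types_a = np.array(types, dtype=np.int64)
    lengths_a = np.array(lengths, dtype=float)
    diams_a = np.array(diams, dtype=float)

    # compartment centers: cumulative length, then shift so the center node
    # (index 11 of 21, 1-based) sits at z = 0
    edges = np.concatenate([[0.0], np.cumsum(lengths_a)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    node_idx = np.flatnonzero(types_a == NODE)
    centers -= centers[node_idx[N_NODES // 2]]

    geom = FiberGeometry(
        fiber_diameter=d,
        axon_diameter=row["axonD"],
        node_diameter=row["nodeD"],
        internodal_length=L,
        flut_length=row["flutL"],
        stin_length=stin_len,
        n_lamellae=row["nl"],
        comp_types=types_a,
        lengths=lengths_a,
        diameters=diams_a,
        z_offsets=centers,
        node_indices=node_idx,
    )
    # periodicity sanity: node spacing equals L exactly
    assert np.allclose(np.diff(centers[node_idx]), L)
    return geom


def place_axon(geometry: FiberGeometry, center_node_position) -> np.ndarray:
    """3D coordinates (n_comp, 3) of compartment centers for a fiber whose
    center node of Ranvier sits at ``center_node_position`` (µm).  The fiber
    runs parallel to z, so all compartments share the center's (x, y)."""
    c = np.asarray(center_node_position, dtype=float)
    if c.shape != (3,):
        raise ValueError("center_node_position must be a 3-vector")
    coords = np.tile(c, (geometry.n_compartments, 1))
    coords[:, 2] += geometry.z_offsets
    return coords
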