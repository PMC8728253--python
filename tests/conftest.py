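"""Shared fixtures and independent geometric oracles.

The oracles deliberately use different algorithms from the production code
(scalar trigonometry for torsions, brute-force pairwise loops for contacts)
so that agreement between the two routes is evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from kinconf.conformation import load_centroid_table
from kinconf.fixtures import fixture_for_state


# ----------------------------------------------------------------- oracles

def oracle_torsion(p1, p2, p3, p4) -> float:
    """Torsion by explicit projection into the plane normal to the central
    bond; independent of the arctan2-of-cross-products implementation."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b = b / np.linalg.norm(b)
    u = (p1 - p2) - np.dot(p1 - p2, b) * b   # component of bond 1 in plane
    v = (p4 - p3) - np.dot(p4 - p3, b) * b   # component of bond 3 in plane
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    cosang = np.clip(np.dot(u, v), -1.0, 1.0)
    ang = math.degrees(math.acos(cosang))
    # sign: right-handed rotation about b from u to v
    if np.dot(np.cross(u, v), b) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


def oracle_region_counts(ligand, chain, residue_indices, cutoff=4.0):
    """Brute-force heavy-atom pair count and minimum distance to a region."""
    n = 0
    min_d = math.inf
    for la in ligand.atoms:
        if la.is_hydrogen:
            continue
        for i in residue_indices:
            if not (0 <= i < len(chain.residues)):
                continue
            for pa in chain.residues[i].atoms:
                if pa.is_hydrogen:
                    continue
                d = float(np.linalg.norm(la.position - pa.position))
                min_d = min(min_d, d)
                if d <= cutoff + 1e-9:
                    n += 1
    return n, min_d


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def centroid_table():
    return load_centroid_table()


@pytest.fixture(scope="session")
def state_fixtures(centroid_table):
    """One synthetic chain per shipped centroid state."""
    return {
        state: fixture_for_state(state, centroid_table)
        for state in centroid_table.entries
    }
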