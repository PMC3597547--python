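import numpy as np
import pytest

from tissuesim.core import RandomStream


@pytest.fixture
def stream():
    return RandomStream(42)


@pytest.fixture
def random_points_2d(stream):
    return stream.uniform(0, 1, size=(30, 2))


def circumcircle_contains(tri_pts, p, tol=1e-9):
    """Brute-force empty-circumcircle oracle: is p strictly inside the
    circumcircle of the triangle tri_pts (3x2)?"""
    ax, ay = tri_pts[0]
    bx, by = tri_pts[1]
    cx, cy = tri_pts[2]
    px, py = p
    m = np.array([
        [ax - px, ay - py, (ax - px) ** 2 + (ay - py) ** 2],
        [bx - px, by - py, (bx - px) ** 2 + (by - py) ** 2],
        [cx - px, cy - py, (cx - px) ** 2 + (cy - py) ** 2],
    ])
    # orient the triangle CCW so the determinant sign is meaningful
    orient = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    det = np.linalg.det(m)
    return det * np.sign(orient) > tol
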