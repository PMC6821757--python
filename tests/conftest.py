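import numpy as np
import pytest

from endoquant.containers import ImagePlane
from endoquant.synthgen import _splat_gaussian


@pytest.fixture
def spot_plane():
    """Factory: plane with Gaussian spots at given (x_um, y_um, photons)."""

    def _make(spots, shape=(64, 64), background=10.0, pixel_size_um=0.1,
              sigma_um=0.2, noise_seed=None):
        img = np.full(shape, float(background))
        for x, y, ph in spots:
            _splat_gaussian(img, x / pixel_size_um, y / pixel_size_um, ph,
                            sigma_um / pixel_size_um)
        if noise_seed is not None:
            img = np.random.default_rng(noise_seed).poisson(img).astype(float)
        return ImagePlane(img, pixel_size_um)

    return _make


def brute_force_linking(pa: np.ndarray, pb: np.ndarray, max_disp: float):
    """Exhaustive optimal radius-gated partial matching (oracle).

    Minimizes sum of squared displacements over linked pairs plus
    max_disp^2 for every unlinked spot, over all one-to-one partial
    matchings restricted to pairs closer than max_disp.  Returns
    (best_cost, best_links).
    """
    n, m = len(pa), len(pb)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    gate2 = max_disp**2
    best = {"cost": np.inf, "links": []}

    def recurse(i, used_b, cost, links):
        if cost >= best["cost"]:
            return
        if i == n:
            total = cost + gate2 * (m - len(links))
            if total < best["cost"]:
                best["cost"] = total
                best["links"] = list(links)
            return
        # leave spot i unlinked
        recurse(i + 1, used_b, cost + gate2, links)
        for j in range(m):
            if j not in used_b and d2[i, j] < gate2:
                links.append((i, j))
                recurse(i + 1, used_b | {j}, cost + d2[i, j], links)
                links.pop()

    recurse(0, frozenset(), 0.0, [])
    return best["cost"], sorted(best["links"])


def linking_cost(pa, pb, links, max_disp):
    """Objective value of a given link set under the same convention."""
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    cost = sum(d2[i, j] for i, j in links)
    return cost + max_disp**2 * (len(pa) - len(links) + len(pb) - len(links))
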