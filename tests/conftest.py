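import numpy as np
import pytest

from lungseg.phantom import PhantomConfig, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """64-px phantoms: the smallest size the 5-stage network accepts is 32,
    but 64 leaves room for visible anatomy."""
    return PhantomConfig(image_size=64)


@pytest.fixture(scope="session")
def phantom_sample(small_phantom_config):
    return generate_phantom(small_phantom_config, seed=7)


@pytest.fixture(scope="session")
def phantom_dataset(small_phantom_config):
    return generate_dataset(12, small_phantom_config, seed=5)


# ---------------------------------------------------------------------------
# independent oracles (pure-python BFS / set arithmetic), shared by unit and
# acceptance tests
# ---------------------------------------------------------------------------

def bfs_components(mask: np.ndarray, connectivity: int = 8):
    """Label foreground components by BFS; returns list of sets of (r, c)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                queue = [(r, c)]
                seen[r, c] = True
                comp = set()
                while queue:
                    cr, cc = queue.pop()
                    comp.add((cr, cc))
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                comps.append(comp)
    return comps


def oracle_keep_largest(mask: np.ndarray, k: int) -> np.ndarray:
    """Reference connected-domain filter: BFS labels, sort by (-area,
    first raster index), keep k."""
    comps = bfs_components(mask, connectivity=8)
    w = mask.shape[1]
    ranked = sorted(comps, key=lambda comp: (-len(comp), min(r * w + c for r, c in comp)))
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in ranked[:k]:
        for r, c in comp:
            out[r, c] = True
    return out


def oracle_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Reference flood fill: BFS 4-connected background from the border;
    everything else becomes foreground."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    reach = np.zeros_like(mask)
    queue = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and not mask[r, c]
    ]
    for r, c in queue:
        reach[r, c] = True
    while queue:
        r, c = queue.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc] and not reach[nr, nc]:
                reach[nr, nc] = True
                queue.append((nr, nc))
    return ~reach


def oracle_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Set-overlap reference for the five metrics."""
    pred_set = {tuple(p) for p in np.argwhere(np.asarray(pred, dtype=bool))}
    truth_set = {tuple(p) for p in np.argwhere(np.asarray(truth, dtype=bool))}
    n = np.asarray(pred).size
    tp = len(pred_set & truth_set)
    fp = len(pred_set - truth_set)
    fn = len(truth_set - pred_set)
    tn = n - tp - fp - fn
    return {
        "accuracy": (tp + tn) / n,
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "dice": 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else 1.0,
        "jaccard": tp / (tp + fp + fn) if tp + fp + fn else 1.0,
    }


def finite_difference_grad(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = f(x)
        flat[i] = orig - h
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * h)
    return g
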