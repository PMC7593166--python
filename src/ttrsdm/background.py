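"""Environmental zonation and occurrence-sample design.

Cells are classified into environmental zones by clara-style k-medoids
(repeated PAM on random subsamples, keeping the medoid set with the lowest
total dissimilarity over all rows, Euclidean distance on z-scored
variables).  Presences are thinned to a maximum count spread as evenly as
possible across occupied zones, and pseudoabsences are drawn in equal
halves from the training region (stratified by the zones occurring there)
and from the test region (stratified by all zones), so the background spans
environments beyond the training domain.  The identical pseudoabsence set
is handed to every model being compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ZoneModel:
    """k-medoids zonation in standardized environmental space."""

    medoids: np.ndarray      # (k, p) in standardized coordinates
    mean: np.ndarray
    scale: np.ndarray
    columns: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.medoids)

    def assign(self, env_table) -> np.ndarray:
        """Zone index of each row: nearest medoid (pure function of the
        environmental vector, no spatial information)."""
        Z = (self._as_matrix(env_table) - self.mean) / self.scale
        d = ((Z[:, None, :] - self.medoids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def total_dissimilarity(self, env_table) -> float:
        Z = (self._as_matrix(env_table) - self.mean) / self.scale
        d = np.sqrt(((Z[:, None, :] - self.medoids[None, :, :]) ** 2).sum(axis=2))
        return float(d.min(axis=1).sum())

    def _as_matrix(self, env_table) -> np.ndarray:
        if isinstance(env_table, pd.DataFrame):
            return env_table[list(self.columns)].to_numpy(float)
        return np.asarray(env_table, float)


def _pam(D: np.ndarray, k: int, max_sweeps: int = 10) -> np.ndarray:
    """Exact PAM (BUILD + SWAP) on a precomputed distance matrix."""
    n = D.shape[0]
    medoids: list[int] = [int(D.sum(axis=1).argmin())]
    dist_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(dist_near[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        new = int(gain.argmax())
        medoids.append(new)
        dist_near = np.minimum(dist_near, D[new])
    medoids_arr = np.array(medoids)
    for _ in range(max_sweeps):
        Dm = D[medoids_arr]                      # (k, n)
        order = np.argsort(Dm, axis=0)
        nearest = order[0]
        d1 = Dm[nearest, np.arange(n)]
        d2 = Dm[order[1], np.arange(n)]
        best_delta, best_swap = 0.0, None
        non_medoids = np.setdiff1d(np.arange(n), medoids_arr)
        for mi in range(len(medoids_arr)):
            mine = nearest == mi
            base = np.where(mine, d2, d1)        # cost if medoid mi removed
            for h in non_medoids:
                delta = np.minimum(base, D[h]).sum() - d1.sum()
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids_arr[best_swap[0]] = best_swap[1]
    return medoids_arr


def cluster_environments(env_table, k: int = 24, subsample_size: int = 200,
                         seed: int = 0, n_draws: int = 5) -> ZoneModel:
    """clara-style k-medoids zonation.

    Runs PAM on ``n_draws`` random subsamples of ``subsample_size`` rows and
    keeps the medoid set with the lowest total dissimilarity over the full
    table.  Variables are z-scored internally.
    """
    if isinstance(env_table, pd.DataFrame):
        columns = tuple(env_table.columns)
        Xr = env_table.to_numpy(float)
    else:
        Xr = np.asarray(env_table, float)
        columns = tuple(f"v{i}" for i in range(Xr.shape[1]))
    n = Xr.shape[0]
    if n < k:
        raise ValueError("need at least k rows")
    if len(np.unique(Xr, axis=0)) < k:
        raise ValueError("k exceeds the number of distinct rows")
    mean = Xr.mean(axis=0)
    scale = Xr.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (Xr - mean) / scale
    rng = np.random.default_rng(seed)
    best: ZoneModel | None = None
    best_cost = np.inf
    size = min(subsample_size, n)
    for _ in range(n_draws):
        idx = rng.choice(n, size=size, replace=False)
        sub = Z[idx]
        if len(np.unique(sub, axis=0)) < k:
            continue
        D = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        med = _pam(D, k)
        cand = ZoneModel(medoids=sub[med], mean=mean, scale=scale,
                         columns=columns)
        cost = cand.total_dissimilarity(Xr)
        if cost < best_cost:
            best, best_cost = cand, cost
    if best is None:
        raise ValueError("no subsample contained k distinct rows")
    return best


def _even_quota(available: np.ndarray, total: int) -> np.ndarray:
    """Spread ``total`` draws as evenly as possible over groups.

    Base quota ``total // n_groups`` each, remainder to the groups with the
    most available records; a group never receives more than it has, and
    capacity freed by small groups is redistributed.
    """
    g = len(available)
    quota = np.minimum(available, total // g)
    # redistribute leftovers to groups with spare records, largest first
    while quota.sum() < min(total, available.sum()):
        spare = available - quota
        order = np.argsort(-spare, kind="stable")
        for i in order:
            if quota.sum() >= min(total, available.sum()):
                break
            if spare[i] > 0:
                quota[i] += 1
                spare[i] -= 1
    return quota


def thin_presences(presences: pd.DataFrame, zones: np.ndarray,
                   max_n: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Thin presences to at most ``max_n``, evenly across occupied zones."""
    if max_n < 1:
        raise ValueError("max_n must be at least 1")
    if len(presences) == 0:
        raise ValueError("empty presence set")
    if len(presences) <= max_n:
        return presences.copy()
    zones = np.asarray(zones)
    rng = np.random.default_rng(seed)
    occupied, counts = np.unique(zones, return_counts=True)
    quota = _even_quota(counts, max_n)
    keep: list[np.ndarray] = []
    for z, q in zip(occupied, quota):
        rows = np.flatnonzero(zones == z)
        keep.append(rng.choice(rows, size=q, replace=False))
    idx = np.sort(np.concatenate(keep))
    return presences.iloc[idx].copy()


def sample_pseudoabsences(grid, zone_model: ZoneModel, n_total: int,
                          seed: int = 0, species: str = "virtual") -> pd.DataFrame:
    """Equal-count background: half inside, half outside the training region.

    ``floor(n_total / 2)`` points come from training-region cells stratified
    evenly over the zones occurring there; the remaining points come from
    test-region cells stratified over all zones occurring on the grid.
    Pseudoabsence points may fall in presence cells.
    """
    if n_total < 2:
        raise ValueError("n_total must be at least 2")
    rng = np.random.default_rng(seed)
    zones_all = zone_model.assign(grid.env_table())
    parts = []
    for region, n_part in (("training", n_total // 2),
                           ("test", n_total - n_total // 2)):
        cells = grid.cells(region)
        if cells.size == 0:
            raise ValueError(f"region {region!r} has no cells")
        z = zones_all[cells]
        occupied, counts = np.unique(z, return_counts=True)
        # stratified evenly; cells may repeat so capacity is unbounded
        quota = np.full(len(occupied), n_part // len(occupied))
        remainder_order = np.argsort(-counts, kind="stable")
        for i in remainder_order[: n_part - quota.sum()]:
            quota[i] += 1
        for zone, q in zip(occupied, quota):
            pool = cells[z == zone]
            pick = rng.choice(pool, size=q, replace=q > len(pool))
            parts.append(pick)
    cell_idx = np.concatenate(parts)
    return pd.DataFrame({
        "species": species,
        "lon": grid.lon[cell_idx],
        "lat": grid.lat[cell_idx],
        "presence": 0,
        "region": grid.region[cell_idx],
        "cell": cell_idx,
        "zone": zones_all[cell_idx],
    })
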