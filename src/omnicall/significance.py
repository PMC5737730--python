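"""Binomial mismapping significance model.

A breakpoint cluster (or candidate SNV) supported by x reads at a position
with physical depth n is scored by the probability that at least x of the n
fragments are mismappings, with per-read mismapping probability
p = 10^(-m/10) derived from the mapping-quality threshold m (default 20,
so p = 0.01):

    p_bc = Pr(X >= x),  X ~ Binomial(n, p).

Tail probabilities are computed in log space and cached in precomputed
tables up to ``n_max``; deeper positions fall through to direct computation.
"""

from __future__ import annotations

import hashlib
import json
import math
import tempfile
import warnings
from pathlib import Path

import numpy as np

DEFAULT_MAPQ_THRESHOLD = 20
DEFAULT_N_MAX = 1000
DEFAULT_ALPHA = 1e-5

_TABLE_VERSION = 1


def mismap_probability(mapq_threshold: float) -> float:
    """Per-read mismapping probability implied by a phred MAPQ threshold."""
    return 10.0 ** (-mapq_threshold / 10.0)


def _log_pmf_vector(n: int, p: float) -> np.ndarray:
    """log Binomial(n, p) pmf at k = 0..n."""
    k = np.arange(n + 1, dtype=float)
    logc = (
        math.lgamma(n + 1)
        - np.array([math.lgamma(v + 1) for v in k])
        - np.array([math.lgamma(n - v + 1) for v in k])
    )
    return logc + k * math.log(p) + (n - k) * math.log1p(-p)


def tail_probability(n: int, x: int, p: float) -> float:
    """Pr(X >= x) for X ~ Binomial(n, p), via log-space summation.

    x = 0 returns 1 exactly; x > n returns 0 exactly.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"mismapping probability must be in (0, 1), got {p}")
    if n < 0 or x < 0:
        raise ValueError("n and x must be non-negative")
    if x == 0:
        return 1.0
    if x > n:
        return 0.0
    logp = _log_pmf_vector(n, p)[x:]
    m = logp.max()
    return float(min(1.0, math.exp(m) * np.exp(logp - m).sum()))


def _sf_row(n: int, p: float) -> np.ndarray:
    """Vector of Pr(X >= x) for x = 0..n (reverse cumulative of the pmf)."""
    pmf = np.exp(_log_pmf_vector(n, p))
    sf = np.cumsum(pmf[::-1])[::-1]
    sf[0] = 1.0
    return np.minimum(sf, 1.0)


class SignificanceModel:
    """Tail-probability tables for one mapping-quality threshold.

    Rows are built lazily per depth n and cached to disk keyed by
    (m, n_max); a corrupt cache is rebuilt with a warning.
    """

    def __init__(
        self,
        mapq_threshold: float = DEFAULT_MAPQ_THRESHOLD,
        n_max: int = DEFAULT_N_MAX,
        alpha: float = DEFAULT_ALPHA,
        cache_dir: str | Path | None = None,
    ) -> None:
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        self.mapq_threshold = float(mapq_threshold)
        self.p = mismap_probability(mapq_threshold)
        self.q = 1.0 - self.p
        self.n_max = int(n_max)
        self.alpha = float(alpha)
        self._cache_dir = Path(cache_dir) if cache_dir is not None else None
        self._table: dict[int, np.ndarray] | None = None

    # -- table construction / cache ------------------------------------

    def _default_cache_dir(self) -> Path:
        return Path(tempfile.gettempdir()) / "omnicall-tables"

    def _cache_path(self) -> Path:
        base = self._cache_dir or self._default_cache_dir()
        return base / f"binom_m{self.mapq_threshold:g}_n{self.n_max}_v{_TABLE_VERSION}.json"

    def build_tables(self, persist: bool = True) -> dict[int, np.ndarray]:
        """Build (or load) Pr(X >= x) rows for all n <= n_max."""
        if self._table is not None:
            return self._table
        path = self._cache_path()
        if path.exists():
            try:
                self._table = self._load_cache(path)
                return self._table
            except Exception:
                warnings.warn(f"corrupt significance table cache {path}; rebuilding")
        table = {n: _sf_row(n, self.p) for n in range(0, self.n_max + 1)}
        self._table = table
        if persist:
            try:
                self._save_cache(path, table)
            except OSError:
                pass
        return table

    def _save_cache(self, path: Path, table: dict[int, np.ndarray]) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        flat = np.concatenate([table[n] for n in range(self.n_max + 1)])
        payload = flat.tobytes()
        header = {
            "version": _TABLE_VERSION,
            "m": self.mapq_threshold,
            "n_max": self.n_max,
            "sha256": hashlib.sha256(payload).hexdigest(),
            "values": flat.tolist(),
        }
        path.write_text(json.dumps(header))

    def _load_cache(self, path: Path) -> dict[int, np.ndarray]:
        header = json.loads(path.read_text())
        if header["version"] != _TABLE_VERSION or header["n_max"] != self.n_max:
            raise ValueError("cache metadata mismatch")
        flat = np.asarray(header["values"], dtype=float)
        if hashlib.sha256(flat.tobytes()).hexdigest() != header["sha256"]:
            raise ValueError("cache checksum mismatch")
        table: dict[int, np.ndarray] = {}
        off = 0
        for n in range(self.n_max + 1):
            table[n] = flat[off : off + n + 1]
            off += n + 1
        if off != flat.size:
            raise ValueError("cache truncated")
        return table

    # -- lookup ---------------------------------------------------------

    def lookup(self, n: int, x: int) -> float:
        """Pr(X >= x | depth n); table lookup, direct computation beyond n_max."""
        if x <= 0:
            return 1.0
        if x > n:
            return 0.0
        if n <= self.n_max:
            return float(self.build_tables()[n][x])
        return tail_probability(n, x, self.p)

    def score_cluster(self, cluster, depth: int) -> float:
        """Score a breakpoint cluster: p_bc at its (rounded) weighted support.

        Fractional support is rounded half-up; support exceeding depth is
        clamped with a warning (indicates a depth-accounting problem).
        """
        x = int(math.floor(cluster.support + 0.5))
        n = int(depth)
        if x > n:
            warnings.warn(
                f"cluster support {x} exceeds depth {n} at "
                f"{getattr(cluster, 'pos', '?')}; clamping"
            )
            x = n
        p_bc = self.lookup(n, x)
        cluster.p_bc = p_bc
        return p_bc
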