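import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thyromine.discretize import TransactionDB

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_db(rng: np.random.Generator, max_n: int = 200,
              max_items: int = 12) -> TransactionDB:
    """A random class-free transaction database.

    Items are rendered as single-level attributes (``i3=1``) so they form
    valid transactions; transaction density varies so both sparse and
    near-uniform databases appear.
    """
    m = int(rng.integers(1, max_items + 1))
    universe = [f"i{k}=1" for k in range(m)]
    n = int(rng.integers(1, max_n + 1))
    density = rng.uniform(0.2, 0.95)
    rows = []
    for _ in range(n):
        t = {u for u in universe if rng.random() < density}
        if not t:
            t = {universe[int(rng.integers(m))]}
        rows.append(t)
    return TransactionDB.from_itemsets(rows)


def counts_of(frequent) -> dict:
    return {k: v.count for k, v in frequent.items()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def data_dir() -> Path:
    """Directory holding the optional real study datasets (populated by
    scripts/fetch_uci.py; not shipped)."""
    return Path(__file__).resolve().parent.parent / "data"
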