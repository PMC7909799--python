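import numpy as np
import pytest

from defolyr.series import SeasonalRingSeries, SiteCollection


def make_tree(tree_id, first_year, ew, lw, missing=None):
    ew = np.asarray(ew, dtype=float)
    lw = np.asarray(lw, dtype=float)
    return SeasonalRingSeries(
        tree_id=tree_id,
        core_ids=[tree_id + "a"],
        first_year=first_year,
        earlywood=ew,
        latewood=lw,
        total=ew + lw,
        missing_flags=missing,
    )


def flat_collection(n_trees=20, n_years=60, first_year=1950, ew=0.7, lw=0.3):
    """Constant-width stand: no growth change anywhere."""
    trees = [
        make_tree(f"T{j:02d}", first_year, np.full(n_years, ew), np.full(n_years, lw))
        for j in range(n_trees)
    ]
    return SiteCollection(site_id="flat", trees=trees)


@pytest.fixture
def flat_site():
    return flat_collection()


@pytest.fixture
def single_event_site():
    """20 flat trees; 14 (70%) with a 40% latewood drop in year 31 of the
    span and a 30% earlywood drop in year 32 (defoliation year = year 30)."""
    first = 1950
    n = 60
    trees = []
    for j in range(20):
        ew = np.full(n, 0.7)
        lw = np.full(n, 0.3)
        if j < 14:
            lw[31] *= 1 - 0.4
            ew[32] *= 1 - 0.3
        trees.append(make_tree(f"T{j:02d}", first, ew, lw))
    return SiteCollection(site_id="one_event", trees=trees)
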