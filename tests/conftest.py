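import numpy as np
import pytest

from deadwood.stand_io import PlotWindow, StemMap, StemRecord


@pytest.fixture
def window():
    return PlotWindow(0, 0, 100, 80)


def make_map(
    coords,
    window=None,
    species="chinese_fir",
    status="live_planted",
    dbh=10.0,
    planted_species=("chinese_fir", "michelia"),
    **kwargs,
):
    """Build a StemMap from coordinates; scalar fields broadcast to all stems."""
    window = window or PlotWindow(0, 0, 100, 80)
    n = len(coords)

    def broadcast(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    sp, st, d = broadcast(species), broadcast(status), broadcast(dbh)
    extra = {k: broadcast(v) for k, v in kwargs.items()}
    stems = [
        StemRecord(
            id=f"s{i:05d}",
            x=float(x),
            y=float(y),
            species=sp[i],
            status=st[i],
            dbh=d[i],
            **{k: v[i] for k, v in extra.items()},
        )
        for i, (x, y) in enumerate(coords)
    ]
    return StemMap(window=window, stems=stems, planted_species=planted_species)


@pytest.fixture
def make_stem_map():
    return make_map
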