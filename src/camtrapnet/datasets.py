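"""Bundled data: the published community composition table.

``load_community_table`` returns the printed species list of a 67-camera,
one-year survey of an Asian elephant community: 44 species (28 families,
14 orders) with their photograph counts, printed relative-abundance index,
site occupancy, and the above-mean abundance screen flag.  The printed RAI
column is kept as data (its denominator is not stated in the source table
and is not consistent with a percent-of-total recomputation).

``events_from_community_table`` expands the table's marginals into a
synthetic event list — labelled synthetic: the study's raw site-level records
are not deposited, so events are placed to match each species' total count
and occupancy exactly while site assignments are random.
"""

from __future__ import annotations

from datetime import datetime, timedelta
from importlib import resources

import numpy as np
import pandas as pd

from .detections import DetectionEvent

__all__ = ["load_community_table", "events_from_community_table"]

N_SITES = 67


def load_community_table() -> pd.DataFrame:
    """The bundled community composition table (one row per species)."""
    ref = resources.files("camtrapnet.data").joinpath("nangunhe_community.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["selected"] = df["selected"].astype(bool)
    return df


def events_from_community_table(
    table: pd.DataFrame | None = None,
    n_sites: int = N_SITES,
    seed: int = 0,
) -> list[DetectionEvent]:
    """Synthetic events matching the table's per-species counts and occupancy.

    Each species receives exactly ``n_photographs`` events spread over
    exactly ``occupancy`` distinct sites (each occupied site gets at least
    one event; the remainder are assigned uniformly at random).  Event times
    are placeholders on a regular grid — only the site × species structure is
    meaningful.
    """
    if table is None:
        table = load_community_table()
    rng = np.random.default_rng(seed)
    t0 = datetime(2022, 6, 1)
    events: list[DetectionEvent] = []
    counter = 0
    for row in table.itertuples(index=False):
        n, occ = int(row.n_photographs), int(row.occupancy)
        if not 1 <= occ <= min(n, n_sites):
            raise ValueError(f"{row.species}: occupancy {occ} infeasible for {n} events")
        sites = rng.choice(n_sites, size=occ, replace=False)
        extra = rng.choice(sites, size=n - occ, replace=True)
        for s in np.concatenate([sites, extra]):
            events.append(
                DetectionEvent(
                    site_id=f"S{int(s) + 1:03d}",
                    species=str(row.species),
                    event_start=t0 + timedelta(hours=counter),
                    n_records=1,
                )
            )
            counter += 1
    return events
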