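from datetime import date

import numpy as np
import pytest

from alliancenet.association import AssociationMatrix
from alliancenet.survey_io import (
    Activity,
    AllianceRegistry,
    Survey,
)


def make_survey(sid, members, day=date(2009, 9, 1), activity=Activity.TRAVEL, **kw):
    return Survey(
        survey_id=sid,
        date=day,
        members=frozenset(members),
        activity=activity,
        **kw,
    )


@pytest.fixture
def toy_registry():
    """Two allied alliances (KS, PD) and one outsider (RR) in period T1."""
    return AllianceRegistry(
        second_order={
            "PON": "KS", "QUA": "KS", "MID": "KS",
            "PRI": "PD", "WAB": "PD",
            "SMO": "RR", "URC": "RR",
        },
        first_order_units={
            "T1": (
                frozenset({"PON", "QUA", "MID"}),
                frozenset({"PRI", "WAB"}),
                frozenset({"SMO", "URC"}),
            )
        },
        third_order_pairs={"T1": frozenset({frozenset({"KS", "PD"})})},
    )


def random_matrix(rng, ids):
    """Random symmetric HWI matrix over `ids`."""
    k = len(ids)
    vals = rng.uniform(0, 1, size=(k, k))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return AssociationMatrix(ids=tuple(ids), values=vals)


def block_matrix(ids_by_block, within, between, rng=None, noise_sd=0.0):
    """Planted block-structured HWI matrix."""
    ids = [i for block in ids_by_block for i in block]
    block_of = {i: b for b, block in enumerate(ids_by_block) for i in block}
    k = len(ids)
    vals = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            base = within if block_of[ids[a]] == block_of[ids[b]] else between
            if noise_sd and rng is not None:
                base = float(np.clip(base + rng.normal(0, noise_sd), 0, 1))
            vals[a, b] = vals[b, a] = base
    return AssociationMatrix(ids=tuple(ids), values=vals)
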