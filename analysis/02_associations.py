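#!/usr/bin/env python
"""Filter the simulated surveys and compute half-weight index matrices.

Applies the standard filters (rest/travel/social activity, August-December,
same-day resight removal), classifies each survey's alliance-level content,
and writes the pooled HWI matrix per period.  Run 01_simulate_society.py
first.
"""

from collections import Counter
from pathlib import Path

from alliancenet.association import association_matrix, permutation_null
from alliancenet.survey_io import (
    classify_survey_level,
    filter_surveys,
    load_registry,
    read_surveys,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for period in ("T1", "T3"):
        outdir = OUT / f"sim_{period}"
        surveys = read_surveys(outdir / "surveys.csv")
        kept = filter_surveys(surveys)
        registry = load_registry(outdir / "registry.yaml")
        levels = Counter(
            classify_survey_level(s, registry, period)[0].value for s in kept
        )
        ids = sorted(set().union(*(s.members for s in kept)))
        matrix = association_matrix(kept, ids, period=period)
        matrix.to_csv(outdir / "hwi.csv")
        perm = permutation_null(kept[:300], n_perm=200, seed=1)
        print(
            f"[{period}] kept {len(kept)}/{len(surveys)} surveys; "
            f"levels: {dict(levels)}"
        )
        print(
            f"  preferential association: CV(HWI) obs={perm.observed:.3f} "
            f"null={perm.null_mean:.3f} p={perm.p_value:.4f}"
        )


if __name__ == "__main__":
    main()
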