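#!/usr/bin/env python
"""Long-term clonal evolution after a bridge event: subclones, breakpoint
sharing, and the sloping bulk copy-number transition.

Expands a bridge-breakage daughter with continued BFB on its uncapped end,
deduplicates subclonal CN profiles, classifies breakpoint sharing
(ancestral / subset / private), and fits the bulk profile around the
eroding terminus with the step-vs-slope model selector.
"""

import os
from collections import Counter

import pandas as pd

from bridgecascade import (
    CascadeConfig,
    CoverageModel,
    classify_breakpoint_sharing,
    default_genome,
    detect_sloping_transition,
    emulate_bulk,
    expand_clone,
    run_cascade,
    subclone_profiles,
    truth_cn_profile,
)

SEED = 4
OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    genome = default_genome(SEED)
    cfg = CascadeConfig(
        seed=SEED, p_fragmentation=0.0, p_tst=0.0, second_wave_breaks_mean=0.0,
        p_mitotic_second_wave=0.0, p_micronucleus_broken=0.0,
        p_micronucleus_unbroken=0.0, p_bfb_continue=0.9, p_stabilize=0.02,
    )
    lin = run_cascade(genome, cfg, 1, seed=SEED)
    founder = lin.cells_at(1)[1]  # the loss daughter carries the uncapped stub
    pop = expand_clone(genome, founder, 8, cfg, seed=SEED, cap=300)
    cells = pop.cells[:200]

    profs = subclone_profiles(cells, genome, 250_000)
    sharing = Counter()
    if len(profs) >= 2:
        for s in classify_breakpoint_sharing(profs, genome, 250_000):
            sharing[s.label] += 1

    truths = [truth_cn_profile(c, 250_000, genome) for c in cells]
    bulk = emulate_bulk(truths, CoverageModel())
    fit = detect_sloping_transition(bulk.counts[("chrA", "A")][40:160], bin_size=250_000)

    os.makedirs(OUT, exist_ok=True)
    rows = [
        {"quantity": "population_size", "value": len(pop.cells)},
        {"quantity": "unique_cn_profiles", "value": len(profs)},
        {"quantity": "largest_subclone_cells", "value": profs[0].n_cells},
        {"quantity": "bulk_transition_call", "value": fit.kind},
        {"quantity": "ramp_width_mb",
         "value": round((fit.ramp_bounds[1] - fit.ramp_bounds[0]) * 0.25, 2)
         if fit.kind == "slope" else 0.0},
    ] + [{"quantity": f"breakpoints_{k}", "value": v} for k, v in sorted(sharing.items())]
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "population_evolution.tsv"), sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nstaggered terminal losses across subclones blur the bulk copy-number "
        "step into a gradual slope — a bulk-sequencing fingerprint of ongoing "
        "instability"
    )


if __name__ == "__main__":
    main()
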