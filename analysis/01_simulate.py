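#!/usr/bin/env python
"""Generate the two synthetic study systems with planted ground truth.

Produces the five-basin "open-like" and six-basin "closed-like" ensembles
(4 conditions x 2 runs x 150 frames each, 213-atom seven-domain miniature),
writes every run as a multi-model PDB plus per-frame state labels and the
generator spec, and reports the planted close-contact occupancies.
"""

from pathlib import Path

import numpy as np

from mdscape.synthetic_data import (
    closedlike_ensemble,
    generate_trajectory,
    openlike_ensemble,
    save_run,
    state_contact_flags,
    stationary_distribution,
)

SEED = 17
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name, factory in (("open_like", openlike_ensemble), ("closed_like", closedlike_ensemble)):
        spec = factory(seed=SEED)
        outdir = RESULTS / name / "runs"
        runs = generate_trajectory(spec)
        labels = np.concatenate([g.labels for _, g in runs])
        for traj, truth in runs:
            save_run(traj, truth, outdir)
        flags = state_contact_flags(spec)
        pi = stationary_distribution(spec.transition)
        print(f"{name}: {len(runs)} runs, {len(labels)} frames, K={spec.n_states}")
        print(f"  stationary occupancies: {np.round(pi, 3)}")
        print(f"  contact states (CTD-tower < 8 A): {np.flatnonzero(flags).tolist()}, "
              f"planted contact occupancy {flags[labels].mean():.3f}")


if __name__ == "__main__":
    main()
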