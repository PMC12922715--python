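#!/usr/bin/env python
"""Generate the synthetic behavioural study used by the downstream analyses.

Writes two trial tables under results/:

* study_trials.csv — a miniature study (2 human-like observers sharing a
  latent image-difficulty axis, 1 "model" observer on an independent axis;
  2 presentation times x 2 corruptions, 40 trials per cell), the input for
  the error-consistency and psychometric analyses;
* full_design_preview.csv — the first rows of one observer's full-scale
  session structure, demonstrating that the complete design (6 times x 3
  corruptions, 48/96-image sets over 2 sessions of 2 rounds) yields
  exactly 5,760 trials per observer.
"""

import argparse
from pathlib import Path

from error_consistency.simulate import (
    DesignSpec, ObserverSkill, miniature_design, simulate_trial_table,
)
from error_consistency.trials import write_trials


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    design = miniature_design(seed=args.seed, n_human=2, n_model=1)
    table = simulate_trial_table(design, seed=args.seed + 100)
    write_trials(table, args.out_dir / "study_trials.csv")
    print(f"miniature study: {len(table)} trials, "
          f"{table['observer_id'].nunique()} observers, "
          f"{int(table['is_practice'].sum())} practice rows "
          f"-> {args.out_dir / 'study_trials.csv'}")

    full = DesignSpec(observers=(ObserverSkill("demo_observer"),))
    full_table = simulate_trial_table(full, seed=args.seed)
    assert len(full_table) == full.n_trials_per_observer() == 5760
    write_trials(full_table.head(200), args.out_dir / "full_design_preview.csv")
    print(f"full design: {len(full_table)} trials/observer "
          f"(2*2*(2*3*48 + 4*3*96)); preview of 200 rows "
          f"-> {args.out_dir / 'full_design_preview.csv'}")


if __name__ == "__main__":
    main()
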