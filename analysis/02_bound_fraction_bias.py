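"""Quantify the seven-jump bound-fraction bias on simulated tracking data.

Simulates 500,000 molecules at the recovery-study conditions (50% bound and
static, D_free = 2.5 μm²/s, 700 nm slice in a 4 μm illuminated slab of an
8 μm nucleus, σ = 35 nm, Δτ ≈ 4.45 ms, photobleaching tuned to a mean
observed track length of ~3 frames), fits the two-state displacement model
to the first seven jumps of every trajectory, and reports how far the
fitted bound fraction falls below the true 50%. Writes
results/bound_fraction_bias.json.
"""

import json
from pathlib import Path

from smtk.replay import bound_fraction_bias_stage

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    out = bound_fraction_bias_stage(seed=seed, n_traj=500_000, n_restarts=8)
    print(
        f"mean track length {out['mean_track_length']:.2f}; "
        f"F_bound_hat = {out['F_bound_hat']:.3f} (truth 0.500); "
        f"underestimate {out['bias_percentage_points']:.2f} percentage points"
    )
    OUT.mkdir(exist_ok=True)
    (OUT / "bound_fraction_bias.json").write_text(json.dumps(out, indent=1, default=float))


if __name__ == "__main__":
    main()
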