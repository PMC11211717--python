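"""Temporal-generalization metrics on simulated decoding matrices.

Generates subject ensembles of train-time x test-time decoding-precision
matrices with either a stable (rank-one) or a dynamic (time-localized)
code, computes the delay-window off-diagonal sums (plain and wide-shift),
and runs the across-subject sign-flip permutation test for dynamic coding
with joint FDR correction.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wmdrift.synth import gen_tgm
from wmdrift.tgm import dynamic_coding_test, offdiag_sum, wide_offdiag_sum

RESULTS = Path(__file__).resolve().parents[1] / "results"
WINDOW = (0.5, 1.5)
SEED = 3


def main() -> None:
    rows = []
    masks = {}
    for code in ("stable", "dynamic"):
        mats, _ = gen_tgm(20, code=code, snr=8.0, rng_seed=SEED)
        off = [offdiag_sum(m, WINDOW) for m in mats]
        wide = [wide_offdiag_sum(m, WINDOW, 0.5) for m in mats]
        test = dynamic_coding_test(mats, window=WINDOW, n_perm=2000, rng_seed=SEED)
        masks[code] = test
        rows.append(
            {"code": code,
             "offdiag_sum_mean": np.mean(off), "offdiag_sum_sem": np.std(off) / np.sqrt(len(off)),
             "wide_sum_mean": np.mean(wide),
             "n_dynamic_elements": int(test.dynamic.sum()),
             "n_elements": len(test)}
        )
        test.to_csv(RESULTS / f"dynamic_coding_{code}.csv", index=False)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "tgm_summary.csv", index=False)
    print(summary.round(3).to_string(index=False))
    print("a stable code keeps its off-diagonal sum and flags no dynamic "
          "elements; a dynamic code collapses the wide-shift sum and is "
          "flagged across the suppressed region.")


if __name__ == "__main__":
    main()
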