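"""Validate the pseudo-IPD path: simulate, digitize, reconstruct, refit.

Simulates both trial arms at the reported medians (EFS 9 vs 6 months, OS
19 vs 13), samples each Kaplan-Meier curve on a half-month grid with
numbers at risk — the digitized-figure stand-in — reconstructs pseudo
individual-patient data, refits exponential curves, and reports how well
the medians are recovered.  Writes results/reconstruction.csv.
"""

from pathlib import Path

import pandas as pd
from lifelines import KaplanMeierFitter

from mbcea import TrialSpec, fit_parametric, km_inputs_from_trial, \
    reconstruct_ipd, simulate_trial

OUT = Path(__file__).resolve().parent.parent / "results"
N = 2000  # large arm so sampling noise does not mask digitization error


def main() -> None:
    rows = []
    for arm, (m_efs, m_os), seed in (("T+I+B", (9.0, 19.0), 1),
                                     ("T+I", (6.0, 13.0), 2)):
        spec = TrialSpec(n_per_arm=N, efs_median=m_efs, os_median=m_os,
                         admin_censor_time=24.0, seed=seed)
        records = simulate_trial(spec)
        km = km_inputs_from_trial(records, grid_step=0.5)
        for endpoint, target in (("efs", m_efs), ("os", m_os)):
            ipd = reconstruct_ipd(km[endpoint])
            km_median = KaplanMeierFitter().fit(
                ipd.time, ipd.event).median_survival_time_
            row = {"arm": arm, "endpoint": endpoint.upper(),
                   "target_median": target,
                   "reconstructed_km_median": round(float(km_median), 3),
                   "relative_error": round(float(km_median) / target - 1.0, 4)}
            if endpoint == "efs":
                # EFS times are exponential by construction, so a parametric
                # refit is also meaningful (OS is a sum of exponentials)
                row["fitted_exp_median"] = round(
                    fit_parametric(ipd, "exponential").median, 3)
            rows.append(row)

    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "reconstruction.csv", index=False)
    print(table.to_string(index=False))
    worst = table["relative_error"].abs().max()
    print(f"\nworst median recovery error at n={N}: {worst:.2%}")


if __name__ == "__main__":
    main()
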