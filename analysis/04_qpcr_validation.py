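#!/usr/bin/env python
"""Cross-validate sequencing rates with a simulated qPCR experiment.

Calibrates a standard curve per assay from a noisy 7-point 10-fold
dilution series, quantifies ten validation samples (nine variants
spanning the dynamic range plus wild type, two experiments averaged on
the copy scale), and reports the concordance R^2 against the sequencing
route plus the Cre-dependence t-test on the non-cleavage rate.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from loxscreen import DesignSpec, RbeVariant, TruthRecord, sample_library
from loxscreen.classify import estimates_from_tally, non_cleavage_rate, tally
from loxscreen.qpcr import (
    DEFAULT_DILUTION_COPIES,
    QpcrMeasurement,
    StandardCurve,
    concordance,
    cre_dependence_test,
    fit_standard_curve,
    quantify,
    rates_from_copies,
    simulate_cq,
)
from loxscreen.simulate import draw_markers, simulate_outcomes, simulate_read_pairs

OUT = Path("results/qpcr")
SEED = 22
TRUE_CURVE = StandardCurve(slope=-3.38, intercept=31.2, r_squared=1.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # per-assay calibration from noisy dilution series
    copies = np.array(DEFAULT_DILUTION_COPIES)
    curves = {}
    for assay in ("NC", "loxP", "lox2272"):
        cq = simulate_cq(TRUE_CURVE, copies, noise_sd=0.15, seed=rng)
        curves[assay] = fit_standard_curve(copies, cq)
        c = curves[assay]
        print(f"standard curve [{assay:7s}]: slope {c.slope:.3f}, "
              f"efficiency {100 * c.efficiency:.1f}%, R^2 {c.r_squared:.4f}")

    # validation truth set: nine variants across the range + wild type
    pool = {v.sequence: v for v in sample_library(DesignSpec(), 40, seed=SEED)}
    pool.pop("TATACGAAGTTAT", None)
    truth = [
        TruthRecord(v, 0.035, float(p), 2000)
        for v, p in zip(list(pool.values())[:9], np.linspace(0.005, 0.59, 9))
    ]
    truth.append(TruthRecord(RbeVariant("TATACGAAGTTAT"), 0.035, 0.5, 2000))

    # sequencing route
    markers = draw_markers(SEED)
    pairs = ((r1, r2) for _, r1, r2 in simulate_read_pairs(truth, markers, seed=SEED))
    est = estimates_from_tally(
        tally(pairs, markers.marker_a, markers.marker_b), cutoff=500
    ).set_index("variant_sequence")
    ngs = [float(est.loc[t.variant.sequence, "cleavage_rate_pct"]) for t in truth]

    # qPCR route: two experiments averaged on the rate scale
    rows, qpcr = [], []
    for t in truth:
        reps = []
        for exp in (1, 2):
            counts = simulate_outcomes(
                TruthRecord(t.variant, t.p_noncleavage, t.p_loxP_given_cleaved, 10_000),
                rng,
            )
            raw = {"NC": counts.n_uncleaved, "loxP": counts.n_loxP_cleaved,
                   "lox2272": counts.n_lox2272_cleaved}
            meas = {
                a: quantify(curves[a],
                            float(simulate_cq(curves[a], [c], noise_sd=0.15, seed=rng)[0]))
                for a, c in raw.items()
            }
            nc, lp = rates_from_copies(
                QpcrMeasurement(t.variant.sequence, meas["NC"], meas["loxP"], meas["lox2272"])
            )
            reps.append(lp)
            rows.append({"variant": t.variant.sequence, "experiment": exp,
                         "non_cleavage_rate_pct": nc, "cleavage_rate_pct": lp})
        qpcr.append(float(np.mean(reps)))
    pd.DataFrame(rows).to_csv(OUT / "qpcr_rates.tsv", sep="\t", index=False)

    r2 = concordance(ngs, qpcr)
    print(f"sequencing vs qPCR concordance: R^2 = {r2:.4f} over {len(truth)} samples")

    # Cre dependence of the non-cleavage rate
    wt = RbeVariant("TATACGAAGTTAT")
    off = [non_cleavage_rate(simulate_outcomes(TruthRecord(wt, 0.98, 0.5, 5000), rng))
           for _ in range(3)]
    on = [non_cleavage_rate(simulate_outcomes(TruthRecord(wt, 0.035, 0.5, 5000), rng))
          for _ in range(3)]
    t_stat, p = cre_dependence_test(off, on)
    print(f"non-cleavage, induction off {np.mean(off):.1f}% vs on {np.mean(on):.1f}%: "
          f"Welch t = {t_stat:.1f}, p = {p:.2e}")
    pd.DataFrame({"ngs_rate_pct": ngs, "qpcr_rate_pct": qpcr}).to_csv(
        OUT / "concordance.tsv", sep="\t", index=False
    )
    print(f"Wrote {OUT}/qpcr_rates.tsv, concordance.tsv")


if __name__ == "__main__":
    main()
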