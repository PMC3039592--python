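"""Preservation QC and dating arithmetic.

Fits the qPCR standard curve on the canonical dilution series, quantifies
template copies from replicate Cts, screens racemization D/L ratios,
averages the two radiocarbon determinations, derives the clock rates for
the three divergence calibrations, and converts the simulated panel's
diversity into a female effective population size.
"""

from pathlib import Path

import numpy as np

from ancientmt import (
    CalibratedRates,
    DatedSample,
    RunConfig,
    average_dates,
    calibrate_rate,
    fit_standard_curve,
    quantify_replicates,
    racemization_check,
    rho_tmrca,
    simulate_modern_panel,
    theta_to_ne,
)
from ancientmt import io as amtio
from ancientmt.config import CALIBRATIONS
from ancientmt.pipeline import (
    DEFAULT_DATES,
    DEFAULT_DL,
    DEFAULT_QPCR_POINTS,
    DEFAULT_QPCR_REPLICATE_COPIES,
)
from ancientmt.reference import ReferenceGenome

SIM_DIR = Path("scratch/analysis")
RES_DIR = Path("results")


def main() -> None:
    cfg = RunConfig.from_yaml(SIM_DIR / "config.yaml")
    curve = fit_standard_curve(DEFAULT_QPCR_POINTS)
    cts = [curve.y_intercept + curve.slope * np.log10(c)
           for c in DEFAULT_QPCR_REPLICATE_COPIES]
    copies, copies_sd = quantify_replicates(cts, curve)
    preservation = racemization_check(DEFAULT_DL)

    dates = [DatedSample(l, a, s) for l, a, s in DEFAULT_DATES]
    mean_date = average_dates(dates)
    weighted = average_dates(dates, weighted=True)

    cal_time, cal_rate = CALIBRATIONS[cfg.calibration]
    base = CalibratedRates(calibration_time=cal_time, rate=cal_rate)
    rates = {name: calibrate_rate(base, t).rate
             for name, (t, _) in sorted(CALIBRATIONS.items())}

    ref = ReferenceGenome(
        id="simref",
        sequence=amtio.read_fasta(SIM_DIR / "reference.fasta")["simref"])
    modern = simulate_modern_panel(ref, n_genomes=cfg.modern_panel_size,
                                   mean_substitutions=cfg.modern_panel_substitutions,
                                   seed=cfg.seed + 200)
    rho = rho_tmrca(modern, ref.sequence, base)
    seqs = list(modern.values())
    pair_d = [sum(a != b for a, b in zip(seqs[i], seqs[j]))
              for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
    theta = float(np.mean(pair_d)) / ref.length
    ne = theta_to_ne(theta, base, cfg.generation_time)

    report = {
        "standard_curve": {"slope": curve.slope,
                           "y_intercept": curve.y_intercept,
                           "r_squared": round(curve.r_squared, 3),
                           "efficiency": round(curve.efficiency, 2)},
        "copies_per_reaction": round(copies),
        "copies_sd": round(copies_sd),
        "racemization_pass": preservation.racemization_pass,
        "racemization_caveat": preservation.caveat,
        "mean_age_bp": mean_date.age,
        "mean_age_weighted_bp": round(weighted.age, 1),
        "calibrated_rates": rates,
        "rho_years": {"estimate": round(rho.age), "lower": round(rho.age_lower),
                      "upper": round(rho.age_upper)},
        "theta_per_site": theta,
        "effective_size_females": round(ne),
    }
    amtio.write_json_report(report, RES_DIR / "05_qc_dating.json")
    print(f"efficiency {curve.efficiency:.2f}; ~{copies:.0f} copies/reaction; "
          f"mean age {mean_date.age:.0f} BP; clock rates "
          + ", ".join(f"{k}={v:.2g}" for k, v in rates.items()))


if __name__ == "__main__":
    main()
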