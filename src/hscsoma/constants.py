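"""Reference constants shared across modules.

The anchor for calibrating neutral (Tier-3) mutation accrual is the
cross-age slope of passenger-mutation accumulation measured in AML
whole genomes, in mutations per year, together with its 95% confidence
interval. Tier 3 denotes the non-conserved, non-coding, non-repetitive
genomic fraction, where mutations are treated as selectively neutral
markers of cell-division history.
"""

#: Reference Tier-3 mutation accumulation slope (mutations/year) from AML
#: whole-genome data, used to calibrate neutral accrual and to delimit the
#: plausible range of mutation parameters.
AML_TIER3_SLOPE = 0.09162

#: 95% confidence interval for :data:`AML_TIER3_SLOPE` (mutations/year).
AML_TIER3_SLOPE_CI = (0.03759, 0.1457)

#: Weeks per year used to convert weekly schedules to annual rates.
WEEKS_PER_YEAR = 52.0

#: Default simulated lifespan: 85 years at 52 weeks/year.
DEFAULT_LIFESPAN_WEEKS = 4420


def calibrated_tier3_rate(
    adult_division_rate_per_week: float, symmetric_division: bool = False
) -> float:
    """Per-division Tier-3 mutation rate anchored to the AML slope.

    Chosen so that, at the adult division rate, neutral accrual in the
    pool proceeds at the reference slope:
    ``rate * realized_mutated_divisions_per_year == AML_TIER3_SLOPE``.

    Under the default asymmetric update a division adds one mutated
    daughter while the self-renewing mother retains her state; with the
    pool at capacity and neutral removal, the pool-mean count then rises
    by ``rate * d / (1 + d)`` per week, where ``d`` is the per-cell
    weekly division probability. Under the symmetric toggle both
    daughters carry a new increment and the realized lineage rate is
    ``2 d / (1 + d)``.

    Parameters
    ----------
    adult_division_rate_per_week
        Adult-plateau expected divisions per cell per week.
    symmetric_division
        Whether divisions produce two independently mutated daughters
        instead of the default mother-plus-one-mutated-daughter update.

    Returns
    -------
    float
        Expected Tier-3 mutations per division at birth (mutation-rate
        fold increase 1).
    """
    d = adult_division_rate_per_week
    if d <= 0:
        raise ValueError("adult division rate must be positive")
    lineage_rate = 2.0 * d / (1.0 + d) if symmetric_division else d / (1.0 + d)
    return AML_TIER3_SLOPE / (WEEKS_PER_YEAR * lineage_rate)
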