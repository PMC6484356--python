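"""A four-animal cohort small enough to check by hand.

Two deaths (ages 400 and 700 days) and two censorings (500 and 900 days),
everyone observed from the starting age of 365 days. The product-limit
estimate steps to 3/4 at the first death and to 3/4 * 1/2 = 0.375 at the
second; the 0.5 crossing interpolates to 600 days. With four animals every
sample-size quality test fails, so the estimate is flagged data deficient
even though a value is reported.
"""

from studbooklife import Exposure, estimate_mle, fit_survival

exposures = [
    Exposure("a", "male", entry_age=365, exit_age=400, event=True),
    Exposure("b", "male", entry_age=365, exit_age=500, event=False),
    Exposure("c", "female", entry_age=365, exit_age=700, event=True),
    Exposure("d", "female", entry_age=365, exit_age=900, event=False),
]

curve, table = fit_survival(exposures)
print("age_days  at_risk  deaths  censored  survival  variance")
for i in range(len(table)):
    print(f"{table.ages[i]:8d}  {table.at_risk[i]:7d}  {table.deaths[i]:6d}"
          f"  {table.censored[i]:8d}  {curve.survival[i]:8.4f}"
          f"  {curve.variance[i]:8.6f}")

result = estimate_mle(curve, table)
print(f"\nmedian life expectancy: {result.mle_days:.0f} days"
      f" = {result.mle_years:.2f} years after the first birthday"
      f" (conditional on surviving to day 365)")
print(f"data deficient: {result.data_deficient}"
      f" (tests passed: {sum(vars(result.tests).values())}/5 —"
      f" four animals cannot support a reliable estimate)")
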