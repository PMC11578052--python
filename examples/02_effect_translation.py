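"""Translate trial blood-pressure effects into transition-probability changes.

Shows the chain the model applies every cycle: a 10-year cumulative
probability becomes an annual one; a per-10 mm Hg hazard ratio is rescaled
log-linearly to a trial's SBP reduction; component effects multiply; and
partial adherence mixes treated and untreated probabilities.
"""

from bpcea import (
    apply_effect_with_adherence,
    apply_multiplier_to_probability,
    combine_effects,
    scale_hazard_ratio,
    ten_year_to_annual,
)

p10 = 0.05  # 10-year probability of a first ischemic stroke
p1 = ten_year_to_annual(p10)
print(f"10-year p = {p10}  ->  annual p = {p1:.6f}")

hr10 = 0.70  # hazard ratio per 10 mm Hg SBP reduction (age 35-44)
hr_salt = scale_hazard_ratio(hr10, 10.0, 2.0)  # salt substitution: -2 mm Hg
hr_drug = scale_hazard_ratio(hr10, 10.0, 5.6)  # drugs (HOPE-3): -5.6 mm Hg
print(f"HR per 10 mm Hg = {hr10}  ->  salt {hr_salt:.4f}, drug {hr_drug:.4f}")

hr_combo = combine_effects([hr_salt, hr_drug])
print(f"combination multiplies: {hr_combo:.4f} (= HR per 7.6 mm Hg)")

treated = apply_multiplier_to_probability(p1, hr_combo)
print(f"annual p under combination: {treated:.6f}")

# 75% drug adherence: mixture of treated and untreated probabilities
partial = apply_effect_with_adherence(p1, hr_drug, fraction=0.75)
print(f"annual p, drug at 75% adherence: {partial:.6f}")
# The multipliers act on rates (p -> 1-(1-p)^hr), so composition is exact
# and probabilities always stay inside [0, 1).
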