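"""Find the salt-substitution price at which it stops being cost-effective.

Bisection over the salt substitute's annual cost until the ICER of salt
substitution vs no intervention equals the willingness-to-pay threshold.
"""

from bpcea import SyntheticSpec, generate_parameter_set, threshold_search, validate_config
from bpcea.model import icer_runner

cfg = validate_config(generate_parameter_set(SyntheticSpec(seed=1)))
pair = icer_runner(cfg, "none", "salt_substitution")
path = "interventions.salt_substitution.annual_cost.value"

base_cost = cfg.interventions[1].annual_cost.value
print(f"base-case salt cost: {base_cost:.2f} USD/y, ICER {pair({}):,.2f} USD/QALY")

cost_at_wtp = threshold_search(
    lambda v: pair({path: v}), cfg.run.wtp_usd, bracket=(0.0, 200.0)
)
print(f"salt cost at WTP {cfg.run.wtp_usd:,.1f}: {cost_at_wtp:.2f} USD/y")
print(f"check: ICER at that cost = {pair({path: cost_at_wtp}):,.2f} USD/QALY")
# Above this annual price the intervention's incremental cost per QALY
# exceeds the GDP-per-capita threshold and it would no longer be adopted.
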