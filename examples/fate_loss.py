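"""Dissolved pesticide run-off loss for one cell, one month, one compound.

The loss indicator multiplies four factors: the run-off/precipitation
ratio, a slope/interception/buffer correction f, the fraction surviving a
3-day soil lag (set by the half-life DT50), and a sorption term driven by
Kd = Koc * %OC/100. Strong sorbers (high Koc) and fast degraders (low DT50)
lose little to run-off.
"""

from pestmap.fate import (
    AiParams,
    CellEnvironment,
    runoff_loss_percent,
    slope_interception_buffer_factor,
    soil_water_coefficient,
)

# a moderately persistent, moderately sorbing insecticide
ai = AiParams(name="example-ai", cas="0000-00-0", ai_class="insecticide",
              koc=1000.0, dt50_soil_days=10.0)

f = slope_interception_buffer_factor(slope_deg=5.71, interception_frac=0.2)
env = CellEnvironment(q_mm=30.0, p_mm=100.0, soc_percent=2.0, f_override=f)

kd = soil_water_coefficient(ai.koc, env.soc_percent)
loss = runoff_loss_percent(env, ai)

print(f"slope/interception factor f = {f:.4f}")
print(f"Kd = {kd:.1f} L/kg (Koc=1000, 2% organic carbon)")
print(f"L%_ro = {loss:.4f} % of the applied amount")
print("-> with 30 mm of run-off out of 100 mm rain, about "
      f"{loss:.2f}% of this compound is available for dissolved transport.")
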