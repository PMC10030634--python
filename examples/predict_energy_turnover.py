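"""Predict the energy turnover of a single flower visit.

A forager sits on a flower in weak sun: thorax at 38 degC, head at
33 degC, abdomen at 28 degC, air at 22 degC, global radiation
250 W m-2. The per-part model (reduced preset) turns these five
measurements into a metabolic-rate estimate and its heat-budget
components.
"""
from beeheat import VisitRecord, conductance_estimate, load_preset, predict_metabolism

visit = VisitRecord(T_hd=33.0, T_th=38.0, T_ab=28.0, T_a=22.0, G=250.0)
coeffs = load_preset("table2b")
pred = predict_metabolism(visit, coeffs)

print(f"model variant        : {coeffs.variant}")
print(f"energy turnover M    : {pred.M_mW[0]:7.2f} mW")
print(f"  radiative loss term: {pred.radiative_loss_term[0] * 1e3:7.2f} mW")
print(f"  radiative gain term: {-pred.radiative_gain_term[0] * 1e3:7.2f} mW")
print(f"  convective term    : {pred.convection[0] * 1e3:7.2f} mW")
print(f"  evaporative term   : {pred.evaporation_term[0] * 1e3:7.2f} mW")

# body mean temperature excess over air -> conductance estimate
T_b = (33.0 + 38.0 + 28.0) / 3
g = conductance_estimate(pred.M_mW[0], T_b, 22.0)
print(f"conductance estimate : {g:7.2f} mW/degC  (M / (T_b - T_a), T_b = {T_b:.1f} degC)")
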