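"""Predict tracheal reference values from demographics and normalize a
measurement.

The published regressions predict reference tracheal diameter (pD), luminal
area (pLA) and wall thickness (pWT) from age, height and sex; dividing a
subject's measured value by its reference removes demographic confounding.
The log base of the published equations is unstated, so it is explicit here
and stamped into the result.
"""

from lungqct import Demographics, normalize, predict_trachea

subject = Demographics(age=75, height=1.63, sex=0)  # cohort-typical male

for base in ("natural", "base10"):
    ref = predict_trachea(subject, base)
    print(f"log base {base:8s}: pD = {ref.pD:7.3f} mm  pLA = {ref.pLA:8.3f} mm^2  "
          f"pWT = {ref.pWT:6.3f} mm")

ref = predict_trachea(subject)  # natural log default
measured_dh = 20.1  # mm, e.g. a tracheal hydraulic diameter
print()
print(f"measured tracheal D_h  = {measured_dh} mm")
print(f"normalized D_h / pD    = {normalize(measured_dh, ref.pD):.4f}")
print()
print("A normalized ratio near 1 means the airway is close to the size the")
print("demographic model predicts; the two log bases give different absolute")
print("references, which is why the base must always be reported.")
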