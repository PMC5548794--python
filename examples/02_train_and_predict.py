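"""Train the population model and predict a 3D cochlea from 4 base measures.

Simulates a measured population, regresses every per-specimen fit
coefficient on the predictors (1, A_a, B_a, A_b, B_b), then predicts the
full 3D lateral-wall curve of a new subject from its four base parameters
alone — the measures available on a conventional clinical CT — and
integrates the curve for its metric length.
"""

from cochleashape import (
    BaseParameters,
    basilar_membrane_length,
    default_config,
    generate,
    metric_length,
    predict,
    train,
)

pop = generate(default_config(n=60, seed=3))
model = train(pop.table, radius_model="polynomial")
print(f"trained on {model.training_n} specimens; M is {model.M.shape[0]}x{model.M.shape[1]} "
      "(predictors x radius powers)")

subject = BaseParameters(A_a=5.1, A_b=3.6, B_a=3.4, B_b=3.2)
pred = predict(model, subject)
L = metric_length(pred)
L_planar = metric_length(pred, include_height=False)

print(f"subject A = {subject.A:.1f} mm, B = {subject.B:.1f} mm")
print(f"predicted angular length : {pred.angular_length:.0f} deg "
      f"({pred.angular_length_turns:.2f} turns)")
print(f"predicted metric length  : {L:.2f} mm along the lateral wall")
print(f"  without height         : {L_planar:.2f} mm (the vertical course adds little)")
print(f"basilar membrane length  : {basilar_membrane_length(L):.2f} mm (87% of lateral wall)")
x, y, z = pred.curve(0.0)
print(f"curve start (alpha=0)    : ({x:.2f}, {y:.2f}, {z:.2f}) mm — on the x-axis, base plane")
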