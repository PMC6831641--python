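"""Two-site binding and wrong-model detection.

A protein with two independent ligand sites (4-state cycle P, PL, LP,
LPL, all K_D = 10 µM, slow exchange) produces four resonances.  Fitting
the correct 4-state scheme recovers the parameters; forcing a 2-state fit
leaves a large residual and a badly biased K_D — the lineshape equivalent
of model comparison by refitting.
"""

from titrshape import FitConfig, fit_model
from titrshape.fixtures import four_state_dataset

data = four_state_dataset(koff_a=5.0, koff_b=5.0, seed=20)

res4 = fit_model(data, FitConfig.four_state(n_starts=5, seed=0, snr=50.0))
res2 = fit_model(data, FitConfig.two_state(n_starts=5, seed=0, snr=50.0))

print("4-state fit (true: kd=10, koff_a=5, koff_b=5):")
for name, value in res4.params.items():
    print(f"  {name:7s} = {value:8.3f}")
print(f"  SSE = {res4.sse:.4f}")

print("\n2-state fit of the same data:")
for name, value in res2.params.items():
    print(f"  {name:7s} = {value:8.3f}")
print(f"  SSE = {res2.sse:.4f}")

print(f"\nSSE ratio (2-state / 4-state) = {res2.sse / res4.sse:.1f}")
# The ratio well above 1 says the simpler scheme cannot reproduce the
# lineshapes: its K_D lands several-fold off while the 4-state fit stays
# near the generating values.
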