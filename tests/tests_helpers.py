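"""Independent brute-force oracles shared by the test suite.

These deliberately recompute parameter and FLOPs totals straight from layer
shape arithmetic, without calling the package's cost module internals.
"""


def brute_force_params(graph):
    total = 0
    for s in graph.layers:
        bias = s.out_channels if s.use_bias else 0
        if s.kind == "conv":
            total += s.kernel_size**2 * s.in_channels * s.out_channels + bias
        elif s.kind == "dwconv":
            total += s.kernel_size**2 * s.in_channels * s.depth_multiplier + bias
        elif s.kind == "pwconv":
            total += s.in_channels * s.out_channels + bias
        elif s.kind == "batchnorm":
            total += 2 * s.out_channels
        elif s.kind == "dense":
            total += s.in_channels * s.out_channels + bias
    return total


def brute_force_flops(graph):
    shapes = graph.shapes()
    total = 0
    for s in graph.layers:
        h = max(shapes[s.name][0], 1)
        if s.kind == "conv":
            total += h * h * (s.in_channels * s.kernel_size**2 + 1) * s.out_channels
        elif s.kind == "dwconv":
            total += h * h * (s.depth_multiplier * s.kernel_size**2 + 1) * s.out_channels
        elif s.kind == "pwconv":
            total += h * h * (s.in_channels + 1) * s.out_channels
        elif s.kind == "dense":
            total += (2 * s.in_channels - 1) * s.out_channels
    return total
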