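"""Independent scalar reference implementation of one behavioral step.

Written without numpy vector operations (plain Python loops, ``math`` and
``fractions``), so it shares no code path with the integration engine.  It
reproduces, for a single simulated fly, the documented step scheme:

  pose update -> exact OU noise update -> wind/opto drive -> n_inner
  substeps of (hDeltaC output, mutual inhibition + adaptation, local
  output, PFL relaxation, heading increment) -> spontaneous-turn event ->
  PFL2 speed readout,

consuming random numbers from the same seeded generator in the same order
(noise normals, event uniform, turn-angle normal).
"""

import math
from fractions import Fraction


def _sigmoid(x, theta, k):
    return 1.0 / (1.0 + math.exp(-(x - theta) / k))


def _w_hdc_exact(n_neurons, n_columns):
    """Overlap matrix via exact rational interval arithmetic."""
    col_w = Fraction(360, n_columns)
    neu_w = Fraction(360, n_neurons)
    half = col_w / 2
    w = [[Fraction(0)] * n_neurons for _ in range(n_columns)]
    for i in range(n_columns):
        lo_i, hi_i = i * col_w, (i + 1) * col_w
        for j in range(n_neurons):
            c = (2 * j + 1) * neu_w / 2
            total = Fraction(0)
            for shift in (-360, 0, 360):
                lo = max(lo_i, c - half + shift)
                hi = min(hi_i, c + half + shift)
                if hi > lo:
                    total += hi - lo
        # row-normalise later
            w[i][j] = total
    for i in range(n_columns):
        s = sum(w[i])
        w[i] = [float(v / s) for v in w[i]]
    return w


def reference_step(params, heading, x, y, speed, state, wind_direction,
                   odor_on, opto_pattern, rng, representation="allocentric"):
    """Advance one behavioral step; returns (heading, x, y, speed, state).

    ``state`` is a dict with keys u, a, n, pfl3_left, pfl3_right, pfl2
    (lists of length n_columns).  ``rng`` is a numpy Generator shared with
    the engine under test.
    """
    p = params
    C, N = p.n_columns, p.n_neurons
    rad = math.pi / 180.0
    cols = [(k + 0.5) * 360.0 / C for k in range(C)]
    neur = [(j + 0.5) * 360.0 / N for j in range(N)]
    w_hdc = _w_hdc_exact(N, C)

    # pose update with current heading/speed
    x = x + p.dt * speed * math.sin(heading * rad)
    y = y + p.dt * speed * math.cos(heading * rad)

    # exact OU update
    decay = math.exp(-p.dt / p.tau_n)
    scale = p.sigma_n * math.sqrt(max(0.0, 1.0 - decay * decay))
    eta = rng.standard_normal((1, C))[0]
    n_state = [state["n"][i] * decay + scale * eta[i] for i in range(C)]

    u = list(state["u"])
    a = list(state["a"])
    pfl = {"l": list(state["pfl3_left"]), "r": list(state["pfl3_right"]),
           "2": list(state["pfl2"])}
    shifts = {"l": p.phase_shift_left_pfl3, "r": p.phase_shift_right_pfl3,
              "2": p.phase_shift_pfl2}

    eu = math.exp(-p.dt_inner / p.tau_u)
    ea = math.exp(-p.dt_inner / p.tau_a)
    ep = math.exp(-p.dt_inner / p.tau_pfl)
    m1i = p.m1 * p.rate_reference_hz * p.dt_inner

    def hdc_out_at(h):
        if odor_on:
            if representation == "allocentric":
                bump = [math.cos((fb - (180.0 - wind_direction)) * rad) + 1.0
                        for fb in neur]
            else:
                ego = (wind_direction - h + 180.0) % 360.0 - 180.0
                ego = 180.0 if ego == -180.0 else ego
                sl = math.sin((ego + 90.0 - p.peak_left) * rad)
                sr = math.sin((ego + 90.0 - p.peak_right) * rad)
                bump = [math.cos((fb - (180.0 - h + p.phase_shift_left_pfn))
                                 * rad) * sl
                        + math.cos((fb - (180.0 - h + p.phase_shift_right_pfn))
                                   * rad) * sr
                        for fb in neur]
        else:
            bump = [0.0] * N
        act = [bump[j] + opto_pattern[j] for j in range(N)]
        shifted = [act[(j - N // 2) % N] for j in range(N)]
        out = []
        for i in range(C):
            tot = sum(w_hdc[i][j] * shifted[j] for j in range(N))
            out.append(_sigmoid(tot, p.theta_hdc, p.k_hdc) + n_state[i])
        return out

    hout = hdc_out_at(heading)
    for _ in range(p.n_inner):
        if representation == "frontal":
            hout = hdc_out_at(heading)
        tgt = [_sigmoid(-p.w_ii * u[(i + C // 2) % C] - p.g_adapt * a[i]
                        + hout[i], p.theta_mi, p.k_mi) for i in range(C)]
        u_new = [tgt[i] + (u[i] - tgt[i]) * eu for i in range(C)]
        a = [u[i] + (a[i] - u[i]) * ea for i in range(C)]
        u = u_new
        local = [hout[i] - u[(i - C // 2) % C] for i in range(C)]
        for key in ("l", "r", "2"):
            inp = [math.cos((cols[i] - (180.0 - heading + shifts[key])) * rad)
                   + 1.0 + local[i] for i in range(C)]
            tgt = [_sigmoid(v, p.theta_pfl, p.k_pfl) for v in inp]
            pfl[key] = [tgt[i] + (pfl[key][i] - tgt[i]) * ep for i in range(C)]
        heading = heading + m1i * (sum(pfl["r"]) - sum(pfl["l"]))

    event = rng.random(1)[0] < p.p_turn
    kick = p.sigma_turn * rng.standard_normal(1)[0]
    heading = (heading + (kick if event else 0.0)) % 360.0
    speed = p.v_base + p.m2 * sum(pfl["2"])

    new_state = {"u": u, "a": a, "n": n_state, "pfl3_left": pfl["l"],
                 "pfl3_right": pfl["r"], "pfl2": pfl["2"]}
    return heading, x, y, speed, new_state
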