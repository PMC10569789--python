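"""Shared helpers for the test suite and acceptance checks."""

import numpy as np

import cftrgate as cg


def intraburst_recovery(seed: int, min_open_events: int = 500):
    """Simulate last-channel segments with the hE1371Q intraburst preset and
    run the 100 Hz idealization chain until >= min_open_events open dwells.

    Returns pooled (P_oB, K_eqB, n_open).
    """
    from cftrgate.gating import B1_O

    scheme = cg.make_preset("hE1371Q").scheme.with_atp_removed()
    rng_seq = np.random.SeedSequence(seed)
    opens, flickers = [], []
    segment = 0
    while sum(len(o) for o in opens) < min_open_events and segment < 20:
        child = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        traj = cg.simulate_trajectory(scheme, duration=70.0, seed=child,
                                      start=B1_O)
        trace = cg.render_single_channel(traj, cg.RecordingSpec(),
                                         seed=child + 1)
        filtered = cg.gaussian_filter(trace, 100.0)
        events = cg.half_amplitude_idealize(filtered, baseline=0.0)
        frame = events.events
        if len(frame) and frame.iloc[-1]["level"] == "closed":
            frame = frame.iloc[:-1]
        opens.append(frame.loc[frame["level"] == "open", "duration_s"].to_numpy())
        flickers.append(frame.loc[frame["level"] == "closed", "duration_s"].to_numpy())
        segment += 1
    o = np.concatenate(opens)
    f = np.concatenate(flickers)
    tau_o, tau_f = o.mean(), f.mean()
    return tau_o / (tau_o + tau_f), tau_o / tau_f, len(o)
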