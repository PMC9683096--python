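"""Scaled-down demo pipeline configuration shared by the tests."""

SMALL_CONFIG = {
    "seed": 11,
    "phantom": {
        "centerline_kind": "arc",
        "length": 40.0,
        "radius": 2.0,
        "circumferential_resolution": 32,
        "axial_resolution": 100,
        "bulges": [
            {"s_center": 14.0, "amplitude": 2.2, "width": 2.8, "direction": [0, 0, 1]},
            {"s_center": 26.0, "amplitude": 2.8, "width": 3.2, "direction": [0, 0, 1]},
        ],
    },
    "proximal_segment": [10.0, 18.0],
    "distal_segment": [21.5, 30.5],
    "restoration": {"circumferential_resolution": 32, "junction_smoothing_steps": 3},
    "wss": {"period": 0.8, "n_times": 40, "tau_base": 4.0, "pulse_amplitude": 0.4,
            "reversal_strength": 0.35, "influence_width": 10.0},
    "vortex": {"enabled": True, "circulation": 60.0, "core_radius": 0.6, "proximity_delta": 4.0},
}
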