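"""retinotrack: decoding diffusive object motion from retinal populations.

A simulation and analysis toolbox for studying how a population of
retinal ganglion cells encodes the trajectory of a diffusively moving
bar: stimulus-trajectory generators, a linear–nonlinear synthetic
retina with ground-truth receptive fields, optimal linear and
L1-regularised trajectory decoders, neural-image (population-vector)
readouts, position–frequency error spectra, coherence-based
information and redundancy estimates, and receptive-field
characterisation.
"""

from retinotrack.trajectory import (
    BarGeometry,
    LowpassWhiteParams,
    SpringOUParams,
    Trajectory,
    bar_profile,
    diffusion_constant,
    simulate_lowpass_white,
    simulate_spring_ou,
    spring_ou_stationary_var,
)

__version__ = "0.1.0"


def __getattr__(name):
    # lazy access to the heavier submodule API from the package root
    _map = {
        "LinearDecoder": "decoding", "LagGrid": "decoding",
        "CellModel": "retina", "PopulationConfig": "retina",
        "SpikeTrainSet": "retina", "make_population": "retina",
        "encode": "retina",
    }
    if name in _map:
        import importlib

        return getattr(importlib.import_module(f"retinotrack.{_map[name]}"), name)
    raise AttributeError(name)


__all__ = [
    "BarGeometry",
    "LowpassWhiteParams",
    "SpringOUParams",
    "Trajectory",
    "bar_profile",
    "diffusion_constant",
    "simulate_lowpass_white",
    "simulate_spring_ou",
    "spring_ou_stationary_var",
    "__version__",
]
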