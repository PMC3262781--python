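"""Deterministic generators of test inputs: random morphologies, toy
cells, Poisson spike trains and circular contour stacks.

Every generator takes an explicit seed and draws from its own
``numpy.random.Generator`` stream, so the same spec always produces a
byte-identical fixture.  Segment parameters are drawn from documented
ranges around standard passive membrane values (RM ≈ 1 Ω·m²,
CM ≈ 0.0164 F/m², RA ≈ 2.5 Ω·m, soma-scale geometry).
"""

from __future__ import annotations

import math

import numpy as np

from .contours import Contour, ContourStack
from .experiment import EventTrain
from .model import ModelContainer

#: documented draw ranges for random-tree segment parameters (SI)
PARAM_RANGES = {
    "RM": (0.5, 2.0),
    "RA": (1.0, 4.0),
    "CM": (0.008, 0.03),
    "DIA": (2e-6, 2e-5),
    "LENGTH": (1e-5, 1e-4),
}


def soma_parameters() -> dict[str, float]:
    """The standard single-segment parameter set used throughout the
    documentation: a 20 µm × 44.7 µm cylinder with RM 1 Ω·m²,
    RA 2.5 Ω·m, CM 0.0164 F/m², leak at −80 mV, resting at −68 mV."""
    return {
        "Vm_init": -0.0680,
        "RM": 1.000,
        "RA": 2.50,
        "CM": 0.0164,
        "ELEAK": -0.0800,
        "DIA": 2e-05,
        "LENGTH": 4.47e-05,
    }


def single_soma(inject: float = 0.0) -> ModelContainer:
    """A container holding ``/cell`` with the standard soma."""
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    soma = nmc.create_segment("/cell/soma")
    soma.set_parameters(soma_parameters())
    soma.set_parameter("INJECT", inject)
    return nmc


def ball_and_stick() -> ModelContainer:
    """Soma plus one thin dendritic cylinder."""
    nmc = single_soma()
    dend = nmc.create_segment("/cell/soma/dend")
    dend.set_parameters({**soma_parameters(),
                         "DIA": 2e-06, "LENGTH": 1e-04})
    return nmc


def random_tree(n: int, seed: int, cellpath: str = "/cell") -> ModelContainer:
    """A random dendritic tree of ``n`` segments.

    Each new segment attaches to a uniformly chosen existing one;
    parameters are drawn from :data:`PARAM_RANGES`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nmc = ModelContainer()
    nmc.create_cell(cellpath)
    paths = []

    def draw_params() -> dict[str, float]:
        p = {name: float(rng.uniform(lo, hi))
             for name, (lo, hi) in PARAM_RANGES.items()}
        p["ELEAK"] = -0.0800
        p["Vm_init"] = -0.0680
        return p

    soma = nmc.create_segment(f"{cellpath}/soma")
    soma.set_parameters(draw_params())
    paths.append(f"{cellpath}/soma")
    for k in range(1, n):
        parent = paths[int(rng.integers(0, len(paths)))]
        path = f"{parent}/s{k}"
        seg = nmc.create_segment(path)
        seg.set_parameters(draw_params())
        paths.append(path)
    return nmc


def poisson_train(rate: float, T: float, seed: int) -> EventTrain:
    """Homogeneous Poisson spike times on (0, T] at ``rate`` Hz."""
    if rate <= 0 or T <= 0:
        raise ValueError("rate and T must be positive")
    rng = np.random.default_rng(seed)
    times = []
    t = 0.0
    while True:
        t += float(rng.exponential(1.0 / rate))
        if t > T:
            break
        times.append(t)
    return EventTrain(times)


def circle_stack(r: float, h: float, N: int, vertices: int = 64,
                 start_section: int = 0) -> ContourStack:
    """``N`` regular-polygon approximations of a circle of radius ``r``,
    each a section of thickness ``h``."""
    if r <= 0 or h <= 0 or N < 1:
        raise ValueError("r, h must be positive and N >= 1")
    pts = tuple(
        (r * math.cos(2 * math.pi * k / vertices),
         r * math.sin(2 * math.pi * k / vertices))
        for k in range(vertices))
    contours = tuple(
        Contour(section=start_section + i, thickness=h, points=pts)
        for i in range(N))
    return ContourStack(contours)
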