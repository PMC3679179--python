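"""Adaptive nonlocal alternating Bregman restoration.

Same residual-feedback outer loop as the TV solver, but the denoise
sub-step uses nonlocal TV on a patch-similarity graph that is rebuilt from
the current *deblurred* iterate (whose structures are close to the ideal
image even while its noise is re-colored), with a per-pixel bandwidth map
derived from the local power against a precomputed oversmoothed reference.

Per outer iteration (the deblur/denoise pair alternates ``inner_iters``
times, like the TV solver; the graph is rebuilt once per scheduled outer
iteration from the first fresh deblurred iterate):

1. ``u``  <- deblur step on the residual-augmented data;
2. ``h``  <- local_h(local_power(u, reference));
3. ``W``  <- NL-means weights of ``u`` with bandwidth ``h`` (on scheduled
   iterations; otherwise the previous graph is reused);
4. ``g``  <- nonlocal-TV denoise of ``u`` on ``W``;
5. Bregman add-back ``f_{k+1} = f_k + (f - A u)``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .adaptive import AdaptiveHConfig, local_h, local_power, oversmoothed_reference
from .bregman import (
    BregmanState,
    RestorationResult,
    SolverConfig,
    deblur_step,
    relative_difference,
)
from .degradation import PSFKernel, as_image, convolve
from .nonlocal_tv import NLConfig, WeightGraph, compute_nl_weights, nl_chambolle_denoise

__all__ = ["restore_nltv_adaptive", "weight_update_schedule"]


def weight_update_schedule(cfg: NLConfig, outer_iter: int) -> bool:
    """Whether to recompute the weight graph at outer iteration ``outer_iter``.

    The default (``weight_every=1``) rebuilds every iteration; with
    ``weight_every=n`` the graph is rebuilt on iterations 0, n, 2n, ... and
    reused in between.
    """
    if outer_iter < 0:
        raise ValueError("outer_iter must be >= 0")
    return outer_iter % cfg.weight_every == 0


def restore_nltv_adaptive(
    f: np.ndarray,
    kernel: PSFKernel,
    cfg: SolverConfig | None = None,
    nl_cfg: NLConfig | None = None,
    ah_cfg: AdaptiveHConfig | None = None,
    graph_override: WeightGraph | None = None,
) -> RestorationResult:
    """Restore a blurred, noisy image by adaptive nonlocal Bregman iteration.

    Parameters mirror :func:`bregrestore.bregman.restore_tv`; ``nl_cfg``
    controls the patch-similarity graph and ``ah_cfg`` the adaptive
    bandwidth.  ``graph_override`` freezes the weight graph (skipping the
    reference, bandwidth and weight computations entirely) — used for
    degeneration checks against the local solver.
    """
    if cfg is None:
        cfg = SolverConfig()
    if nl_cfg is None:
        nl_cfg = NLConfig()
    if ah_cfg is None:
        ah_cfg = AdaptiveHConfig()
    f = as_image(f)

    expected = None
    if graph_override is None:
        expected = oversmoothed_reference(f, kernel, ah_cfg, solver_cfg=cfg)

    state = BregmanState(u=f.copy(), g=f.copy(), f_k=f.copy())
    graph: WeightGraph | None = graph_override
    converged = False
    iterations = 0

    for k in range(cfg.max_outer):
        u_prev = state.u
        for inner in range(cfg.inner_iters):
            state.u = deblur_step(state.f_k, state.g, kernel, cfg)
            if graph_override is None and inner == 0 and (
                graph is None or weight_update_schedule(nl_cfg, k)
            ):
                hmap = local_h(local_power(state.u, expected, ah_cfg), ah_cfg)
                graph = compute_nl_weights(state.u, replace(nl_cfg, h=hmap.values))
            state.g = nl_chambolle_denoise(
                state.u,
                graph,
                cfg.gamma_couple,
                tol=cfg.denoise_tol,
                max_iter=cfg.denoise_max_iter,
            )
        Au = convolve(state.u, kernel)
        state.f_k = state.f_k + (f - Au)
        state.residual_history.append(float(np.linalg.norm(f - Au)))
        reldiff = relative_difference(u_prev, state.u)
        state.reldiff_history.append(reldiff)
        iterations = k + 1
        if reldiff <= cfg.outer_tol:
            converged = True
            break

    return RestorationResult(
        restored=state.g, state=state, iterations_used=iterations, converged=converged
    )
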