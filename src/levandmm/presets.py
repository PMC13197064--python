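"""Packaged per-regime kinetic parameter sets.

Three presets cover the initial-sucrose regimes the model distinguishes:
``low`` (<= 100 g/L), ``high`` (>= 250 g/L) and the fitted ``transition``
set used around 200 g/L.  The growth- and expression-side constants
(mu_max, alpha, Y_XS, the transfructosylation vmax) carry the fitted
values reported for the strain; the remaining enzymatic constants
(half-saturation constants, hydrolysis/degradation vmax, death rate,
degradation onset) are NON-AUTHORITATIVE placeholders chosen once to give
realistic batch trajectories — levan maxima of tens of g/L, biomass near
2 gDW/L, sucrose depletion at ~12-18 h (low regime) and ~36 h (high
regime).  Levansucrase activity constants are shared across regimes;
only growth/expression parameters differ.
"""

from __future__ import annotations

from .kinetic_core import KineticParameterSet

# Enzymatic constants held identical across regimes.  The sucrose-only
# transfructosylation route is weak (large KM_trans1); the
# fructose-acceptor route carries most levan synthesis, so hydrolysis
# runs first, builds the free-fructose pool, and transfructosylation then
# overtakes it — stronger the higher the sucrose load.  This reproduces
# the observed inverse relation between the H/T ratio and (initial)
# sucrose concentration and the early fructose spike at high sucrose.
_SHARED_ENZYME = dict(
    vmax_hyd=1.2,        # mmol/(mg h), placeholder
    KM_hyd=60.0,         # mM, placeholder
    vmax_trans1=6.42,    # mmol/(mg h), fitted (both terms share the value)
    KM_trans1=5000.0,    # mM, placeholder (weak sucrose-only route)
    vmax_trans2=6.42,
    KM_trans2=8.0e3,     # mM^2, placeholder (fructose-acceptor route dominates)
    vmax_levdeg=0.15,    # mmol/(mg h), placeholder
    KM_levdeg=50.0,      # mM, placeholder
)

LOW = KineticParameterSet(
    mu_max=0.2454,       # 1/h, fitted
    Ks=20.0,             # mM, placeholder
    kd=0.01,             # 1/h, placeholder
    Y_XS=0.040,          # gDW/mmol, placeholder
    alpha=18.19,         # mg/gDW, fitted
    t_levdeg_onset=18.0,  # h, placeholder (degradation after depletion)
    regime_label="low",
    **_SHARED_ENZYME,
)

HIGH = KineticParameterSet(
    mu_max=0.1,          # 1/h, fitted
    Ks=20.0,
    kd=0.005,
    Y_XS=0.010,
    alpha=45.0,          # mg/gDW, fitted
    t_levdeg_onset=36.0,
    regime_label="high",
    **_SHARED_ENZYME,
)

TRANSITION = KineticParameterSet(
    mu_max=0.2454,       # 1/h, fitted (low-like growth)
    Ks=20.0,
    kd=0.01,
    Y_XS=0.015,          # gDW/mmol, fitted (~0.015)
    alpha=45.0,          # mg/gDW, fitted (high-like expression)
    t_levdeg_onset=24.0,
    regime_label="transition",
    **_SHARED_ENZYME,
)

PRESETS: dict[str, KineticParameterSet] = {
    "low": LOW,
    "high": HIGH,
    "transition": TRANSITION,
}
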