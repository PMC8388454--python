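"""Reference values from the summer monitoring study the pipeline targets.

A summer-long monitoring campaign on a Mediterranean Holstein dairy farm
produced fitted circadian equations for five collar-detected behaviors under
no-stress (NS, lowest heat-load quartile) and heat-stress (HS, highest
quartile) conditions, plus the heat-load quartile boundaries observed on that
farm.  These parameter sets serve two roles here: canonical defaults for the
synthetic-data generator (they define the ground truth the simulator embeds)
and worked-example inputs for the model evaluator.

Phase conventions: all phases are stored as additive radian offsets, i.e.
``cos(2*pi/T * h - d)`` in a published equation becomes ``d_stored = -d``.
"""

from __future__ import annotations

from .circadian import CircadianModel

__all__ = [
    "STUDY_QUARTILE_BOUNDARIES",
    "REFERENCE_MODELS",
    "FORM_BY_BEHAVIOR",
    "BEHAVIORS",
    "MODELLED_BEHAVIORS",
]

#: THI_load quartile boundaries (b1, b2, b3) observed in the reference study;
#: dividing by 24 gives the equivalent mean hourly THI of each boundary.
STUDY_QUARTILE_BOUNDARIES: tuple = (1658.76, 1722.80, 1775.30)

#: Six collar behavior states, in canonical column order.
BEHAVIORS = (
    "eating",
    "rumination",
    "rest",
    "mid_activity",
    "high_activity",
    "heavy_breathing",
)

#: Behaviors with their own circadian model (activity = mid + high aggregated).
MODELLED_BEHAVIORS = ("eating", "rumination", "rest", "activity", "heavy_breathing")

#: Model form used for each behavior: multi-peak behaviors driven by milking
#: and feed delivery get the free-period double harmonic, single-peak
#: behaviors the 24-h single harmonic.
FORM_BY_BEHAVIOR = {
    "eating": "double",
    "rumination": "double",
    "rest": "single",
    "activity": "single",
    "heavy_breathing": "single",
}

#: Fitted circadian models by behavior and stress group (minutes per hour).
REFERENCE_MODELS: dict = {
    "eating": {
        "NS": CircadianModel("double", mu=8.77, a=4.114, b=2.052, period1=9.82,
                             c=2.814, d=-3.84, period2=5.922, behavior="eating"),
        "HS": CircadianModel("double", mu=8.142, a=3.710, b=-1.325, period1=6.19,
                             c=5.006, d=0.964, period2=10.56, behavior="eating"),
    },
    "rumination": {
        "NS": CircadianModel("double", mu=23.133, a=-4.330, b=-97.534, period1=18.628,
                             c=-5.150, d=1.827, period2=12.473, behavior="rumination"),
        "HS": CircadianModel("double", mu=22.137, a=-0.386, b=-12.284, period1=1.808,
                             c=-2.660, d=1.334, period2=11.220, behavior="rumination"),
    },
    "rest": {
        "NS": CircadianModel("single", mu=16.247, a=-2.466, b=-2.763, behavior="rest"),
        "HS": CircadianModel("single", mu=13.371, a=-4.872, b=-2.680, behavior="rest"),
    },
    "activity": {
        "NS": CircadianModel("single", mu=7.503, a=2.496, b=-2.568, behavior="activity"),
        "HS": CircadianModel("single", mu=7.796, a=2.735, b=-2.313, behavior="activity"),
    },
    "heavy_breathing": {
        "NS": CircadianModel("single", mu=1.476, a=0.608, b=-2.565, behavior="heavy_breathing"),
        "HS": CircadianModel("single", mu=5.71, a=4.492, b=-2.535, behavior="heavy_breathing"),
    },
}
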