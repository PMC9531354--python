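"""Published calibration summaries for the URRBMI satisfaction instrument.

The validation survey behind the instrument (1,909 respondents; 574 used
for item selection, 1,335 for model evaluation) is not publicly released,
but its summary statistics are: the outer loadings of every measurement
variable, the latent correlation matrix, and the structural coefficients.
These are inputs for replaying the measurement- and structural-assessment
suite (composite reliability, AVE, Fornell-Larcker, adjusted R^2, effect
sizes, effect decomposition) without the raw data.
"""

import pandas as pd

__all__ = [
    "N_TOTAL", "N_CONSTRUCTION", "N_EVALUATION", "N_DRAFT_ITEMS",
    "BETA_MIN", "OUTER_LOADINGS", "LATENT_CORRELATIONS",
    "STRUCTURAL_COEFFICIENTS", "STRUCTURAL_PATHS",
    "latent_correlation_frame",
]

N_TOTAL = 1909
N_CONSTRUCTION = 574
N_EVALUATION = 1335
N_DRAFT_ITEMS = 29
#: smallest significant path coefficient from the pilot survey, used in the
#: inverse-square-root sample-size rule
BETA_MIN = 0.11

#: outer loadings of each first-order construct's items (evaluation sample)
OUTER_LOADINGS = {
    "PE": [0.921, 0.943, 0.916],
    "PQ_overall": [1.000],
    "PQ_information": [0.898, 0.924],
    "PQ_service": [0.930, 0.931],
    "PQ_policy": [0.788, 0.783, 0.796, 0.901, 0.903, 0.884, 0.859],
    "PQ_institution": [0.856, 0.836, 0.912, 0.920, 0.869],
    "PV": [0.951, 0.952],
    "PS": [0.925, 0.928, 0.811],
    "PC": [1.000],
    "PT": [0.887, 0.916],
}

#: second-order loadings of the 17 quality items on perceived quality
SECOND_ORDER_LOADINGS = {
    "PQ1": 0.692, "PQ2": 0.595, "PQ3": 0.684, "PQ4": 0.756, "PQ5": 0.761,
    "PQ6": 0.757, "PQ7": 0.731, "PQ8": 0.750, "PQ9": 0.833, "PQ10": 0.836,
    "PQ11": 0.832, "PQ12": 0.801, "PQ13": 0.783, "PQ14": 0.726,
    "PQ15": 0.839, "PQ16": 0.844, "PQ17": 0.794,
}

#: latent correlations among the six top-level constructs (lower triangle)
_CORR = [
    # PQ     PE     PV     PS     PC     PT
    [1.000, 0.567, 0.792, 0.830, -0.286, 0.623],   # PQ
    [0.567, 1.000, 0.585, 0.582, -0.076, 0.515],   # PE
    [0.792, 0.585, 1.000, 0.842, -0.293, 0.625],   # PV
    [0.830, 0.582, 0.842, 1.000, -0.297, 0.633],   # PS
    [-0.286, -0.076, -0.293, -0.297, 1.000, -0.205],  # PC
    [0.623, 0.515, 0.625, 0.633, -0.205, 1.000],   # PT
]
_CORR_NAMES = ["PQ", "PE", "PV", "PS", "PC", "PT"]

#: facet rows of the latent correlation matrix
FACET_CORRELATIONS = {
    #            PQ    overall  info  service policy inst   PE     PV     PS     PC     PT
    "PQ_overall": [0.692, 1.000, 0.499, 0.582, 0.586, 0.597, 0.427, 0.561, 0.584, -0.224, 0.474],
    "PQ_information": [0.705, 0.499, 1.000, 0.616, 0.608, 0.534, 0.342, 0.510, 0.536, -0.138, 0.376],
    "PQ_service": [0.815, 0.582, 0.616, 1.000, 0.666, 0.724, 0.470, 0.609, 0.646, -0.226, 0.475],
    "PQ_policy": [0.937, 0.586, 0.608, 0.666, 1.000, 0.753, 0.486, 0.760, 0.780, -0.286, 0.565],
    "PQ_institution": [0.908, 0.597, 0.534, 0.724, 0.753, 1.000, 0.583, 0.720, 0.776, -0.252, 0.616],
}

#: published structural coefficients (direct paths)
STRUCTURAL_COEFFICIENTS = {
    ("PE", "PQ"): 0.568,
    ("PE", "PV"): 0.204,
    ("PE", "PS"): 0.070,
    ("PQ", "PV"): 0.676,
    ("PQ", "PS"): 0.421,
    ("PV", "PS"): 0.467,
    ("PS", "PC"): -0.243,
    ("PS", "PT"): 0.634,
}

#: structural graph among the six top-level constructs
STRUCTURAL_PATHS = list(STRUCTURAL_COEFFICIENTS)


def latent_correlation_frame() -> pd.DataFrame:
    """The six-construct latent correlation matrix as a DataFrame."""
    return pd.DataFrame(_CORR, index=_CORR_NAMES, columns=_CORR_NAMES)
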