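"""Package-wide physical defaults and vessel presets.

Every literature-derived constant used by the package lives here so the
provenance of a number is always one import away: blood density and the
Carreau–Yasuda constants, the cardiac-cycle timing (1 s period, systolic
peak at 0.14 s), the 140 mmHg systolic / 80 mmHg diastolic pressure levels,
the solver residual target, the wall-shear snapshot report times, and the
vessel diameters of the pre-/post-dissection aorta used as geometry presets.
"""

#: Blood mass density, kg/m^3.
BLOOD_DENSITY = 1060.0

#: Carreau–Yasuda infinite-shear viscosity, Pa·s.
MU_INF = 0.0035
#: Carreau–Yasuda zero-shear viscosity, Pa·s.
MU_ZERO = 0.056
#: Carreau–Yasuda relaxation time constant, s.
LAMBDA_TIME = 3.313
#: Carreau–Yasuda power-law exponent (dimensionless, shear-thinning).
POWER_N = 0.3568

#: SST closure structure constant a1 (standard literature value).
SST_A1 = 0.31
#: SST closure beta-star constant (standard literature value).
SST_BETA_STAR = 0.09

#: Cardiac cycle period, s.
CARDIAC_PERIOD = 1.0
#: Time of the systolic peak within the cycle, s.
SYSTOLIC_PEAK_TIME = 0.14
#: Systolic pressure level, mmHg.
SYSTOLIC_PRESSURE_MMHG = 140.0
#: Diastolic pressure level, mmHg (standard clinical default; not a
#: patient-specific measurement).
DIASTOLIC_PRESSURE_MMHG = 80.0

#: Unit conversion: 1 mmHg in Pa.
MMHG_TO_PA = 133.322

#: Scaled algebraic residual target for the flow solver.
RESIDUAL_TOLERANCE = 1e-5

#: Wall-shear snapshot report times within the cycle, s.
WSS_SNAPSHOT_TIMES = (0.01, 0.14, 0.35, 0.59)

#: Equivalent descending-aorta diameter used for flow-rate validation, mm.
VALIDATION_EQUIVALENT_DIAMETER_MM = 25.2

# Vessel diameters (mm) measured on the pre-dissection scan.
PRE_AD_ASCENDING_DIAMETER_MM = 52.79
PRE_AD_DESCENDING_DIAMETER_MM = 28.44

# Post-dissection lumen diameters (mm): true/false at ascending and
# descending stations.
POST_AD_TRUE_ASCENDING_MM = 23.17
POST_AD_TRUE_DESCENDING_MM = 20.18
POST_AD_FALSE_ASCENDING_MM = 44.55
POST_AD_FALSE_DESCENDING_MM = 19.11

#: Default unrolled vessel length for synthetic domains, mm (order of an
#: adult thoracic aorta centreline; not patient-measured).
DEFAULT_VESSEL_LENGTH_MM = 400.0

#: Default septum (intimal flap) thickness for dissected domains, mm.
DEFAULT_SEPTUM_THICKNESS_MM = 2.5

#: Default tear (arc-length position, opening length) for the dissected
#: preset, mm.
DEFAULT_TEAR_MM = (40.0, 15.0)
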