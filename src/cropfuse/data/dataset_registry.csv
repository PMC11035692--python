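acronym,legacy,reference_year,admin_scope,source_method,validation_level,resolution_deg,maturity,dispatch,Qy,Qa,Qs,Qv,Qr,Qm,Qd
MRF,1,,global,,none,,never,non-government,0,0.5,0.5,0.5,0,0,0.5
SPAM,0,,global,survey+model,indirect,,periodic,non-government,0.667,0.5,0.7,0.5,0,0.5,0.5
GAEZ2015,0,,global,,indirect,,never,non-government,1,0.5,0.5,0.5,0,0,0.5
GEOGLAM,0,,global,,indirect,0.05,never,non-government,0.867,0.5,0.5,0.5,0.400,0,0.5
OIPA,0,,global,,groundtruth,,never,non-government,1,0.5,0.5,1,1.000,0,0.5
RAP,0,,global,satellite,indirect,,never,non-government,1,0.5,0.3,0.5,1.000,0,0.5
EU,0,,national,survey+satellite,groundtruth,,never,non-government,1,1,0.8,1,1.000,0,0.5
SPAMAF,0,,national,survey+model,none,0.0833,periodic,non-government,1,1,0.7,0,0.004,0.5,0.5
AFCAS,0,,national,,none,0.00833,never,non-government,0.933,1,0.5,0,0.901,0,0.5
SASOY,0,,national,survey+satellite,groundtruth,,never,non-government,0.933,1,0.8,1,0.998,0,0.5
MYSTHA,0,,national,satellite,indirect,,never,non-government,1,1,0.3,0.5,0.998,0,0.5
ASIARICE,0,,national,satellite,indirect,0.0045,never,non-government,1,1,0.3,0.5,0.947,0,0.5
CIVGHA,0,,national,survey+satellite,groundtruth,,never,non-government,1,1,0.8,1,1.000,0,0.5
UZBTJK,0,,national,,groundtruth,,never,non-government,1,1,0.5,1,1.000,0,0.5
USA,0,,national,survey+satellite,groundtruth,,annual,government,0.933,1,0.8,1,0.998,1,1
CA,0,,national,survey+satellite,groundtruth,,annual,government,1,1,0.8,1,0.998,1,1
AFG,0,,national,survey+satellite,groundtruth,,never,non-government,1,1,0.8,1,1.000,0,0.5
DEU,0,,national,survey+satellite+model,indirect,,never,non-government,1,1,1,0.5,1.000,0,0.5
CHNWH,0,,national,survey+satellite,groundtruth,,never,non-government,1,1,0.8,1,0.997,0,0.5
CHNMZ,0,,national,satellite,groundtruth,,never,non-government,1,1,0.3,1,0.937,0,0.5
CHNMZWHRI,0,,national,satellite,groundtruth,,never,non-government,1,1,0.3,1,0.941,0,0.5
BGDRICE,0,,national,survey+satellite,groundtruth,,never,non-government,1,1,0.8,1,1.000,0,0.5
BRA,0,,national,survey+satellite,indirect,,never,non-government,1,1,0.8,0.5,0.998,0,0.5
SEN,0,,national,survey+satellite,groundtruth,,never,non-government,1,1,0.8,1,1.000,0,0.5
AU,0,,national,survey+model,none,,periodic,government,0.733,1,0.7,0,0.975,0.5,1
FR,0,,national,satellite,groundtruth,,annual,non-government,0.933,1,0.3,1,1.000,1,0.5
JP,0,,national,survey+satellite,groundtruth,,periodic,government,1,1,0.8,1,1.000,0.5,1
CHNMZSOY,0,,national,survey+satellite,groundtruth,,never,non-government,0.95,1,0.8,1,1.000,0,0.5
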