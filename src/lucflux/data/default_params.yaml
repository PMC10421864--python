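# Default scaling factors for the net CO2 accounting model.
#
# These are documented placeholders spanning published ranges for insular
# Southeast Asian forest/peat landscapes (IPCC wetland/AFOLU guidance and
# tropical peat fire field studies); they are NOT a calibrated site dataset.
# Supply your own file for real accounting runs.
#
# Units: growth and AGB_post in t dry matter ha^-1 (yr^-1); BurnD in m;
# BulkD in kg m^-3; EF_bb / EF_pb in g CO2 per kg dry fuel;
# EF_pd_* in t CO2 ha^-1 yr^-1; BE, R_*, CC_* dimensionless fractions.
globals:
  R_BGB: {min: 0.20, central: 0.25, max: 0.37}      # belowground/aboveground biomass ratio
  R_WDL: {min: 0.10, central: 0.15, max: 0.25}      # (woody debris + litter)/AGB ratio
  CC_L: 0.4560                                      # live-biomass carbon content
  CC_D: 0.4716                                      # dead-wood carbon content
  BurnD: {min: 0.15, central: 0.33, max: 0.51}      # first-fire burned peat depth, m
  DR_schedule: [1.0, 0.55, 0.37, 0.25]              # burn-depth decrease by fire ordinal
  C_CtoCO2: 44/12

categories:
  forest:
    BE: {min: 0.30, central: 0.50, max: 0.70}
    EF_bb: {min: 1500.0, central: 1600.0, max: 1700.0}
    EF_pb: {min: 1450.0, central: 1580.0, max: 1700.0}
    BulkD: {min: 60.0, central: 100.0, max: 140.0}
    EF_pd_drained: {min: 11.0, central: 19.0, max: 28.0}
    EF_pd_undrained: 0.0
    growth: {min: 1.5, central: 3.4, max: 5.0}      # central: IPCC tropical rainforest
    AGB_post: 150.0
  shrub_grass:
    BE: {min: 0.55, central: 0.72, max: 0.88}
    EF_bb: {min: 1550.0, central: 1650.0, max: 1750.0}
    EF_pb: {min: 1450.0, central: 1580.0, max: 1700.0}
    BulkD: {min: 60.0, central: 100.0, max: 140.0}
    EF_pd_drained: {min: 10.0, central: 17.0, max: 25.0}
    EF_pd_undrained: 0.0
    growth: {min: 1.0, central: 2.0, max: 3.5}
    AGB_post: 10.0
  plantation:
    BE: {min: 0.40, central: 0.55, max: 0.70}
    EF_bb: {min: 1500.0, central: 1600.0, max: 1700.0}
    EF_pb: {min: 1450.0, central: 1580.0, max: 1700.0}
    BulkD: {min: 60.0, central: 100.0, max: 140.0}
    EF_pd_drained: {min: 14.0, central: 23.0, max: 35.0}
    EF_pd_undrained: 0.0
    growth: {min: 5.0, central: 10.0, max: 15.0}
    AGB_post: 20.0
  urban:
    BE: {min: 0.10, central: 0.25, max: 0.40}
    EF_bb: {min: 1500.0, central: 1600.0, max: 1700.0}
    EF_pb: {min: 1450.0, central: 1580.0, max: 1700.0}
    BulkD: {min: 60.0, central: 100.0, max: 140.0}
    EF_pd_drained: {min: 8.0, central: 14.0, max: 20.0}
    EF_pd_undrained: 0.0
    growth: 0.0
    AGB_post: 2.0
  water:
    BE: 0.0
    EF_bb: {min: 1500.0, central: 1600.0, max: 1700.0}
    EF_pb: {min: 1450.0, central: 1580.0, max: 1700.0}
    BulkD: {min: 60.0, central: 100.0, max: 140.0}
    EF_pd_drained: 0.0
    EF_pd_undrained: 0.0
    growth: 0.0
    AGB_post: 0.0
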