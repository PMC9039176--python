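# SCORE 10-year fatal cardiovascular risk equations: Weibull baseline
# parameters (alpha, p) and log-hazard-ratio coefficients per cause.
# Source: Conroy RM et al., Estimation of ten-year risk of fatal
# cardiovascular disease in Europe: the SCORE project. Eur Heart J
# 2003;24:987-1003 (statistical appendix).
# Baseline survival: S0(age) = exp(-exp(alpha) * (age - 20)^p)
# Linear predictor: w = beta_chol*(chol - 6) + beta_sbp*(sbp - 120) + beta_smoker*smoker
region,sex,cause,alpha,p,beta_chol,beta_sbp,beta_smoker
low,female,chd,-29.8,6.36,0.24,0.018,0.71
low,female,non_chd,-31.0,6.62,0.02,0.022,0.63
low,male,chd,-22.1,4.71,0.24,0.018,0.71
low,male,non_chd,-26.7,5.64,0.02,0.022,0.63
high,female,chd,-28.7,6.23,0.24,0.018,0.71
high,female,non_chd,-30.0,6.42,0.02,0.022,0.63
high,male,chd,-21.0,4.62,0.24,0.018,0.71
high,male,non_chd,-25.7,5.47,0.02,0.022,0.63
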