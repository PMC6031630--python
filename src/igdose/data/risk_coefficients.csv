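# BEIR VII cancer-incidence EAR model coefficients (report Tables 12-2 and 12-3).
# beta: excess cases per 10^4 person-year-Sv; gamma per decade of e*;
# eta: attained-age power (solid sites); theta per Sv; delta and phi: log(t/25) terms.
# The brain rows carry the BEIR VII "other solid cancer" coefficients: the report
# publishes no brain-specific incidence row. Override by file for site-specific work.
site,sex,beta,gamma,eta,theta,delta,phi,latency_years
brain,M,1.2,-0.41,2.8,,,,5
brain,F,1.3,-0.41,2.8,,,,5
lung,M,2.3,-0.41,5.2,,,,5
lung,F,3.4,-0.41,5.2,,,,5
leukemia,M,1.62,0.29,,0.87,0.0,0.56,2
leukemia,F,0.93,0.29,,0.87,0.0,0.56,2
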