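# Diminishing repressor: N = 15 molecules decaying at mu t* = 2.75,
# Hill regulation with K = 2.6, H = 1; target threshold 15 by t* = 1.
# alpha = auto lets the solver calibrate the maximal production rate so
# the mean first-passage time equals t_star.

[regulator]
k = 0
mu = 2.75
n0 = 15

[regulation]
sign = repressor
alpha = auto
K = 2.6
H = 1

[system]
x_star = 15
t_star = 1.0
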