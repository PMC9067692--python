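# Voluntary-participation run at the moderate outside payoff.
# Only n (group size) and, for voluntary runs, omega must be given;
# everything else defaults to the standard constants.
n = 60
scenario = "voluntary"
omega = 0.925
periods = 2000
burn_in = 1000
replicates = 10
seed = 7
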