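# Versioned biophysical constants and shrinkage priors for the convolution
# (ERP / Jansen-Rit) neural mass model and its spectral observation model.
# All fitted parameters are dimensionless log-scalings with Gaussian priors
# centred on zero; the values below are the prior-mean operating point.
schema_version: 1

sigmoid:
  # Centred sigmoid S(v) = 2*e0/(1+exp(r*(v0-v))) - 2*e0/(1+exp(r*v0))
  e0: 2.5        # half of maximal firing rate, s^-1
  r: 0.56        # slope, mV^-1
  v0: 6.0        # inflection potential, mV

synaptic:
  He: 4.0        # excitatory synaptic gain, mV
  Hi: 32.0       # inhibitory synaptic gain, mV
  tau_e: 0.008   # excitatory kernel time constant, s
  tau_i: 0.016   # inhibitory kernel time constant, s

intrinsic_gains:
  # Connectivity within a source: pyramidal -> stellate (g1),
  # stellate -> pyramidal (g2), pyramidal -> inhibitory interneurons (g3),
  # inhibitory interneurons -> pyramidal (g4).
  g1: 128.0
  g2: 102.4
  g3: 32.0
  g4: 32.0

coupling_prior_means:
  # Extrinsic between-source coupling strength at log-scaling 0, by edge type.
  # Forward connections target the granular (stellate) population, backward
  # connections the supragranular targets (pyramidal + inhibitory
  # interneurons), lateral connections all three.
  forward: 32.0
  backward: 16.0
  lateral: 4.0

innovations:
  # Endogenous neuronal fluctuations driving each source: one-sided power
  # spectral density  g_u(f) = amp * (white_frac + (1-white_frac) * f^-beta)
  # with f clamped below f_clamp Hz.  Units: (input units)^2 / Hz.
  amp: 0.05
  beta: 1.0
  white_frac: 0.5
  f_clamp: 0.5

channel_noise:
  # Observation noise added after the lead field: a channel-specific white
  # + 1/f^beta term (diagonal) and a common term shared by all channels
  # (rank one).  Same spectral form as the innovations.
  specific_amp: 1.0e-8
  common_amp: 5.0e-9
  beta: 1.0
  white_frac: 0.5
  f_clamp: 0.5

prior_variances:
  # Prior variances of the Gaussian log-scaling parameters.  Zero variance
  # means the parameter is fixed at the prior mean (not estimated): the
  # analysis estimates extrinsic coupling only, never intrinsic physiology.
  coupling: 0.5
  intrinsic: 0.0
  sigmoid_slope: 0.0
  innovations_amp: 0.125
  innovations_beta: 0.0
  noise_amp: 0.125
  noise_beta: 0.0
  lead_gain: 0.0625

frequency_grid:
  f_min: 1.0     # Hz
  f_max: 30.0    # Hz
  df: 0.25       # Hz
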