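# Value-gain matrix produced by optoloop.tuning.tune_pid against the
# default transport plant (i_max 10.4, overshoot bound 0.05 of the
# dynamic range, dt 15 s, expression ensemble 0.6/1.0/1.6,
# measurement-noise sigma 0.005, deployment fine-tuning pass on).
# Regenerate with: optoloop tune --out <path>
operating_points:
- 0.1
- 0.3
- 0.5
- 0.7
- 0.9
gains:
- kp: 0.7931303121327431
  ki: 0.009581723581247715
  kd: 0.0
- kp: 1.5828442546700805
  ki: 0.009581723581247715
  kd: 0.0
- kp: 1.5828442546700805
  ki: 0.02965961142075257
  kd: 0.0
- kp: 6.304134293587772
  ki: 0.16152813746142794
  kd: 0.0
- kp: 12.58111384047565
  ki: 0.5
  kd: 0.0
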