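dataset,variant,iterations,kappa_tr,kappa_val,kappa_ts
HMC,CNN_1,15,0.79,0.73,0.74
HMC,CNN_3,7,0.83,0.72,0.71
HMC,CNN_5,7,0.87,0.71,0.7
HMC,CNN_7,5,0.83,0.69,0.69
HMC,CNN_LSTM_3,7,0.81,0.78,0.78
HMC,CNN_LSTM_5,17,0.84,0.79,0.79
HMC,CNN_LSTM_7,27,0.83,0.77,0.77
HMC,CNN_F_1,14,0.78,0.73,0.74
HMC,CNN_F_3,8,0.84,0.71,0.71
HMC,CNN_F_5,6,0.84,0.7,0.7
HMC,CNN_F_7,5,0.85,0.69,0.69
HMC,CNN_LSTM_F_3,7,0.79,0.77,0.77
HMC,CNN_LSTM_F_5,8,0.77,0.75,0.75
HMC,CNN_LSTM_F_7,10,0.76,0.74,0.74
Dublin,CNN_1,10,0.76,0.68,0.68
Dublin,CNN_3,7,0.85,0.66,0.66
Dublin,CNN_5,6,0.89,0.62,0.64
Dublin,CNN_7,7,0.89,0.65,0.67
Dublin,CNN_LSTM_3,8,0.82,0.76,0.77
Dublin,CNN_LSTM_5,9,0.84,0.78,0.79
Dublin,CNN_LSTM_7,9,0.84,0.77,0.77
Dublin,CNN_F_1,14,0.77,0.65,0.65
Dublin,CNN_F_3,8,0.83,0.65,0.64
Dublin,CNN_F_5,8,0.88,0.6,0.61
Dublin,CNN_F_7,13,0.9,0.67,0.66
Dublin,CNN_LSTM_F_3,8,0.81,0.76,0.77
Dublin,CNN_LSTM_F_5,8,0.82,0.78,0.79
Dublin,CNN_LSTM_F_7,9,0.84,0.77,0.78
SHHS,CNN_1,9,0.8,0.76,0.75
SHHS,CNN_3,7,0.89,0.79,0.79
SHHS,CNN_5,7,0.95,0.78,0.79
SHHS,CNN_7,6,0.92,0.76,0.76
SHHS,CNN_LSTM_3,17,0.87,0.83,0.84
SHHS,CNN_LSTM_5,18,0.86,0.83,0.82
SHHS,CNN_LSTM_7,7,0.79,0.78,0.77
SHHS,CNN_F_1,9,0.8,0.77,0.76
SHHS,CNN_F_3,8,0.89,0.79,0.79
SHHS,CNN_F_5,5,0.9,0.78,0.78
SHHS,CNN_F_7,6,0.94,0.78,0.77
SHHS,CNN_LSTM_F_3,10,0.85,0.82,0.83
SHHS,CNN_LSTM_F_5,18,0.86,0.83,0.82
SHHS,CNN_LSTM_F_7,5,0.8,0.79,0.79
Telemetry,CNN_1,14,0.81,0.76,0.76
Telemetry,CNN_3,10,0.88,0.73,0.75
Telemetry,CNN_5,8,0.9,0.73,0.72
Telemetry,CNN_7,6,0.88,0.72,0.7
Telemetry,CNN_LSTM_3,10,0.85,0.8,0.81
Telemetry,CNN_LSTM_5,9,0.85,0.79,0.8
Telemetry,CNN_LSTM_7,8,0.84,0.8,0.8
Telemetry,CNN_F_1,14,0.82,0.77,0.77
Telemetry,CNN_F_3,8,0.87,0.71,0.71
Telemetry,CNN_F_5,9,0.88,0.73,0.73
Telemetry,CNN_F_7,9,0.91,0.73,0.71
Telemetry,CNN_LSTM_F_3,10,0.84,0.81,0.81
Telemetry,CNN_LSTM_F_5,15,0.89,0.82,0.83
Telemetry,CNN_LSTM_F_7,16,0.89,0.82,0.82
DREAMS,CNN_1,9,0.81,0.75,0.76
DREAMS,CNN_3,8,0.92,0.76,0.76
DREAMS,CNN_5,7,0.91,0.75,0.75
DREAMS,CNN_7,5,0.85,0.73,0.73
DREAMS,CNN_LSTM_3,17,0.88,0.84,0.83
DREAMS,CNN_LSTM_5,20,0.9,0.83,0.83
DREAMS,CNN_LSTM_7,5,0.81,0.78,0.78
DREAMS,CNN_F_1,9,0.82,0.76,0.77
DREAMS,CNN_F_3,7,0.91,0.77,0.78
DREAMS,CNN_F_5,7,0.92,0.74,0.75
DREAMS,CNN_F_7,6,0.88,0.73,0.72
DREAMS,CNN_LSTM_F_3,20,0.89,0.84,0.83
DREAMS,CNN_LSTM_F_5,28,0.9,0.84,0.84
DREAMS,CNN_LSTM_F_7,10,0.85,0.81,0.8
ISRUC,CNN_1,17,0.81,0.77,0.76
ISRUC,CNN_3,6,0.83,0.74,0.75
ISRUC,CNN_5,7,0.9,0.73,0.73
ISRUC,CNN_7,6,0.86,0.72,0.73
ISRUC,CNN_LSTM_3,10,0.81,0.8,0.8
ISRUC,CNN_LSTM_5,10,0.8,0.78,0.78
ISRUC,CNN_LSTM_7,6,0.75,0.75,0.75
ISRUC,CNN_F_1,9,0.79,0.76,0.75
ISRUC,CNN_F_3,7,0.84,0.75,0.75
ISRUC,CNN_F_5,7,0.9,0.73,0.73
ISRUC,CNN_F_7,6,0.86,0.71,0.72
ISRUC,CNN_LSTM_F_3,10,0.81,0.79,0.79
ISRUC,CNN_LSTM_F_5,9,0.78,0.77,0.76
ISRUC,CNN_LSTM_F_7,9,0.75,0.74,0.74
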