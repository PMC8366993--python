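dataset,variant,M_HMC,M_Dublin,M_SHHS,M_Telemetry,M_DREAMS,M_ISRUC
HMC,CNN_1,0.77,0.51,0.56,0.53,0.52,0.6
HMC,CNN_3,0.79,0.46,0.6,0.42,0.47,0.56
HMC,CNN_5,0.81,0.37,0.57,0.39,0.44,0.54
HMC,CNN_7,0.78,0.4,0.5,0.34,0.43,0.55
HMC,CNN_LSTM_3,0.8,0.54,0.58,0.51,0.5,0.61
HMC,CNN_LSTM_5,0.82,0.53,0.6,0.5,0.49,0.62
HMC,CNN_LSTM_7,0.81,0.52,0.59,0.52,0.51,0.61
HMC,CNN_F_1,0.76,0.39,0.58,0.49,0.56,0.62
HMC,CNN_F_3,0.79,0.37,0.6,0.48,0.48,0.63
HMC,CNN_F_5,0.79,0.35,0.57,0.42,0.46,0.61
HMC,CNN_F_7,0.79,0.35,0.54,0.37,0.5,0.58
HMC,CNN_LSTM_F_3,0.78,0.38,0.62,0.45,0.55,0.64
HMC,CNN_LSTM_F_5,0.76,0.37,0.63,0.48,0.55,0.65
HMC,CNN_LSTM_F_7,0.75,0.34,0.62,0.47,0.55,0.62
Dublin,CNN_1,0.53,0.73,0.44,0.41,0.53,0.51
Dublin,CNN_3,0.57,0.78,0.5,0.34,0.49,0.57
Dublin,CNN_5,0.52,0.79,0.51,0.32,0.51,0.59
Dublin,CNN_7,0.53,0.81,0.39,0.31,0.49,0.57
Dublin,CNN_LSTM_3,0.54,0.8,0.48,0.38,0.58,0.55
Dublin,CNN_LSTM_5,0.54,0.82,0.5,0.39,0.58,0.55
Dublin,CNN_LSTM_7,0.5,0.81,0.5,0.42,0.57,0.55
Dublin,CNN_F_1,0.2,0.73,0.13,0.03,0.01,0.07
Dublin,CNN_F_3,0.15,0.77,0.1,0.01,0.02,0.05
Dublin,CNN_F_5,0.04,0.78,0.02,0.01,0.03,0.04
Dublin,CNN_F_7,0.04,0.81,0.13,0.01,0.02,0.14
Dublin,CNN_LSTM_F_3,0.24,0.8,0.07,0.02,0.01,0.05
Dublin,CNN_LSTM_F_5,0.22,0.81,0.07,0.01,0.01,0.05
Dublin,CNN_LSTM_F_7,0.17,0.81,0.06,0.01,0.01,0.04
SHHS,CNN_1,0.57,0.5,0.78,0.42,0.59,0.64
SHHS,CNN_3,0.59,0.52,0.86,0.3,0.6,0.63
SHHS,CNN_5,0.55,0.42,0.89,0.27,0.6,0.63
SHHS,CNN_7,0.61,0.4,0.86,0.26,0.6,0.65
SHHS,CNN_LSTM_3,0.54,0.57,0.86,0.42,0.54,0.62
SHHS,CNN_LSTM_5,0.5,0.56,0.85,0.46,0.52,0.67
SHHS,CNN_LSTM_7,0.47,0.53,0.78,0.46,0.56,0.66
SHHS,CNN_F_1,0.68,0.35,0.78,0.43,0.6,0.65
SHHS,CNN_F_3,0.53,0.29,0.85,0.38,0.59,0.65
SHHS,CNN_F_5,0.52,0.32,0.86,0.39,0.58,0.68
SHHS,CNN_F_7,0.52,0.28,0.88,0.31,0.63,0.67
SHHS,CNN_LSTM_F_3,0.68,0.29,0.84,0.4,0.57,0.63
SHHS,CNN_LSTM_F_5,0.66,0.31,0.85,0.39,0.53,0.65
SHHS,CNN_LSTM_F_7,0.67,0.22,0.79,0.41,0.57,0.62
Telemetry,CNN_1,0.67,0.53,0.51,0.79,0.48,0.63
Telemetry,CNN_3,0.6,0.42,0.55,0.81,0.43,0.53
Telemetry,CNN_5,0.6,0.43,0.54,0.83,0.48,0.57
Telemetry,CNN_7,0.5,0.45,0.38,0.82,0.45,0.52
Telemetry,CNN_LSTM_3,0.68,0.59,0.49,0.83,0.45,0.62
Telemetry,CNN_LSTM_5,0.69,0.59,0.5,0.83,0.43,0.64
Telemetry,CNN_LSTM_7,0.67,0.61,0.5,0.82,0.48,0.65
Telemetry,CNN_F_1,0.7,0.39,0.61,0.8,0.44,0.61
Telemetry,CNN_F_3,0.67,0.46,0.57,0.83,0.46,0.62
Telemetry,CNN_F_5,0.63,0.43,0.41,0.83,0.42,0.55
Telemetry,CNN_F_7,0.64,0.44,0.33,0.84,0.46,0.54
Telemetry,CNN_LSTM_F_3,0.72,0.44,0.6,0.83,0.43,0.6
Telemetry,CNN_LSTM_F_5,0.71,0.48,0.62,0.87,0.44,0.63
Telemetry,CNN_LSTM_F_7,0.68,0.44,0.6,0.86,0.44,0.61
DREAMS,CNN_1,0.5,0.56,0.58,0.34,0.79,0.71
DREAMS,CNN_3,0.46,0.52,0.59,0.34,0.86,0.71
DREAMS,CNN_5,0.42,0.33,0.36,0.31,0.85,0.68
DREAMS,CNN_7,0.61,0.51,0.58,0.27,0.81,0.67
DREAMS,CNN_LSTM_3,0.5,0.56,0.54,0.43,0.87,0.73
DREAMS,CNN_LSTM_5,0.41,0.56,0.54,0.47,0.87,0.75
DREAMS,CNN_LSTM_7,0.45,0.5,0.51,0.42,0.8,0.74
DREAMS,CNN_F_1,0.52,0.39,0.66,0.42,0.8,0.7
DREAMS,CNN_F_3,0.59,0.25,0.56,0.46,0.86,0.67
DREAMS,CNN_F_5,0.55,0.36,0.55,0.4,0.86,0.65
DREAMS,CNN_F_7,0.52,0.32,0.58,0.35,0.82,0.71
DREAMS,CNN_LSTM_F_3,0.53,0.32,0.6,0.43,0.87,0.71
DREAMS,CNN_LSTM_F_5,0.55,0.31,0.63,0.46,0.88,0.72
DREAMS,CNN_LSTM_F_7,0.51,0.16,0.6,0.43,0.83,0.71
ISRUC,CNN_1,0.56,0.57,0.6,0.29,0.63,0.79
ISRUC,CNN_3,0.57,0.54,0.64,0.29,0.56,0.8
ISRUC,CNN_5,0.51,0.46,0.63,0.26,0.57,0.84
ISRUC,CNN_7,0.57,0.48,0.54,0.24,0.52,0.81
ISRUC,CNN_LSTM_3,0.54,0.55,0.65,0.36,0.61,0.81
ISRUC,CNN_LSTM_5,0.51,0.55,0.66,0.42,0.58,0.79
ISRUC,CNN_LSTM_7,0.43,0.53,0.6,0.38,0.6,0.75
ISRUC,CNN_F_1,0.68,0.42,0.63,0.42,0.65,0.77
ISRUC,CNN_F_3,0.59,0.35,0.65,0.41,0.61,0.81
ISRUC,CNN_F_5,0.57,0.41,0.66,0.37,0.57,0.84
ISRUC,CNN_F_7,0.55,0.38,0.62,0.35,0.56,0.81
ISRUC,CNN_LSTM_F_3,0.68,0.41,0.68,0.4,0.63,0.8
ISRUC,CNN_LSTM_F_5,0.67,0.43,0.69,0.44,0.61,0.78
ISRUC,CNN_LSTM_F_7,0.66,0.29,0.66,0.43,0.61,0.75
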